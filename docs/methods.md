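# Methods

`atriscan` implements two genome-analysis procedures for bacterial
proteomes — a screen for unique N-terminal extensions (NTEs) in
proteins relative to their homologs, and a membrane-signature census
that places genomes in a two-dimensional plane and flags structural
outliers with bivariate confidence ellipses — together with the
synthetic-data machinery needed to validate both with planted ground
truth. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic validation does and does not
demonstrate.

## The N-terminal extension screen

### Model

A protein carries a *unique N-terminal extension* when its homologs
consistently align only downstream of its N-terminus: the unaligned
N-terminal overhang is present in the query but in none of its
relatives. The screen takes, per query, a set of homolog hit summaries
(from BLASTP tabular output or from the built-in aligner), applies two
strict filters — similarity > 30% and query coverage > 70% — and caps
the survivors at the top 250 by rank score. "Similarity" means BLAST
positives when a `ppos` column is available (or always, for in-house
alignments), percent identity otherwise; the choice is recorded per hit
and overridable. The inequalities are deliberately strict, so boundary
hits at exactly 30% or 70% are excluded.

For each retained hit the *overhang* is the number of query residues
preceding the position homologous to the subject's first residue,
`query_start − subject_start`, clamped at zero. This reduces to
`query_start − 1` whenever the alignment reaches the subject's own
N-terminus, but stays exact when a boundary mismatch causes the local
alignment to trim its first column on both sequences simultaneously —
the dominant error mode under substitution noise. The call takes the
minimum overhang over all retained hits: one homolog whose N-terminus
maps onto the query N-terminus vetoes uniqueness. A `start_quantile`
option (default 0 = minimum) relaxes this to a majority-style rule for
users who prefer a permissive reading.

### Guards and annotations

- **Support.** With fewer than `min_support` (default 10) retained
  hits, a "unique" extension is unfalsifiable; such queries are
  reported with status `insufficient-support` rather than called.
- **Truncation guard.** A local alignment can mimic an NTE by
  truncating a diverged N-terminal region. When subject coordinates
  are available (always, for the built-in aligner and 12-column BLAST
  tabular input), a positive call additionally requires every retained
  alignment to begin within 5 residues of its subject's N-terminus;
  otherwise the call is downgraded to `subject-start-uncertain`.
- **Length range.** Extensions shorter than `min_nte_len` (default 10
  residues) are not called. An optional `max_nte_len` only *flags*
  longer calls as out-of-range — the 10–73 residue span is treated as
  an observed property of real NTEs, not a hard ceiling.
- **Conservation.** Given reciprocal-best-hit ortholog pairs across
  genomes, each positive call lists the other genomes whose ortholog
  also carries a positive call.
- **Paralog pairs.** Protein families (user-supplied, or single-linkage
  components over within-genome hits passing the same >30/>70 filters)
  containing both a conventional member (overhang 0) and an NTE member
  are reported — the dual-FtsZ motif, where a division protein paralog
  gains a membrane-associating extension.

### Built-in aligner

The screen is database-free when run with the built-in aligner:
optimal affine-gap alignment (Biopython `PairwiseAligner`), BLOSUM62,
gap open 11 / extend 1 — BLASTP's defaults, with the BLAST convention
that the first gap residue costs open+extend. Local mode with no
positive-scoring cell is reported as "no hit". In-house hits carry raw
alignment scores; parsed BLAST hits carry bit scores; the two scales
are never ranked together and mixing them is a hard error. The test
suite checks the aligner against an independently written pure-Python
Gotoh dynamic program on hundreds of random pairs, exact score
equality.

No e-values or composition-based statistics are computed: with an
exhaustive exact aligner, raw-score ranking within one search is
sufficient for the screen's top-k step.

## Amphipathicity of extensions

The original route to calling an extension amphipathic — a trained
secondary-structure predictor — is not reimplementable as a rule; the
package substitutes the classical per-residue hydrophobic moment

μ_H = |Σ_k H_k e^(i k δ)| / N

on the Eisenberg normalized consensus scale with δ = 100°/residue and
an 18-residue window (five helical turns). A window is amphipathic
when μ_H ≥ 0.4 and its mean hydrophobicity ≤ 0.4 — the classical
surface-seeking region of the hydrophobic-moment plot. Windows slide
by one; sequences shorter than the window are scored as a single
window; ties go to the leftmost window. Users with per-residue H/E/C
annotations from an external predictor can restrict the scan to
helical stretches, recovering the original route.

## The membrane-signature census

A genome's signature is the point

- **x** — percentage of proteins with ≥ 1 predicted transmembrane
  helix, over the total ORF count;
- **y** — ratio of Sec-signal-peptide percentages called by a
  permissive vs a strict predictor regime (v5like / v4like).

Ratios are computed from unrounded proportions and reported at full
precision (e.g. 9.0/3.4 = 2.647…). A zero strict-regime percentage
leaves the ratio undefined; the genome is flagged, not dropped. By
default a protein predicted both transmembrane and secreted counts in
both numerators.

A reference panel of signatures is modelled as a bivariate normal with
plain sample mean and unbiased sample covariance (standard
confidence-ellipse practice; a minimum-covariance-determinant robust
fit is available but off by default). The level-L ellipse is the
contour where the squared Mahalanobis distance equals the χ² quantile
with 2 degrees of freedom (5.991 at 95%, 13.816 at 99.9%); panels are
fitted per user-declared group, so different reference groups can be
drawn at different levels. A genome is classified by its Mahalanobis
distance against each group model, and its transmembrane-fraction
percentile is the share of reference genomes with *strictly* smaller
TM fraction. Genomes with many membrane proteins and a strong excess
of permissive-regime signal-peptide calls land in the upper right of
this plane, outside the background cloud — the signature associated
with unusual cell-envelope architectures.

Collinear or duplicated panels make the covariance singular; the fit
refuses them, naming the degenerate axis. Fewer than three usable
panel points is an error.

## Built-in predictor stand-ins

Real censuses should use real predictor output (TMHMM-style short
format; two-column signal-peptide summaries). The built-in stand-ins
exist so the machinery runs end to end with no external tools, and
every report labels them `predictor=builtin`; they are transparent
rules, not reimplementations of the external predictors' statistical
models, and genome-scale conclusions should not rest on them.

- **Transmembrane scan:** Kyte–Doolittle hydropathy, 19-residue
  window, window-mean threshold 1.6, segments closer than 5 residues
  merged. Proteins shorter than the window get zero helices.
- **Signal-peptide rules:** secreted iff the first 5 residues have net
  charge ≥ +1, a hydrophobic run of at least `h_min` residues occurs
  within the first 25, and a cleavage position ≤ 35 has small residues
  (A/G/S/C/T) at −3 and −1. The two regimes differ only in `h_min`
  (strict 10 vs permissive 8), so strict calls are a subset of
  permissive calls *on any input* — the genome-level ratio statistic is
  ≥ 1 by construction, reproducing the direction of the discrepancy
  between signal-peptide predictor generations that the census
  statistic is designed around.

## Synthetic data

- **Families** share one uniformly random ancestral core (default 200
  aa, 12 members); members mutate by i.i.d. substitutions only, so a
  planted extension length is exactly recoverable (an optional indel
  rate relaxes this for robustness testing). Planted extensions are
  random or amphipathic (faces I/L/F vs K/R/E assigned by helical
  angle). Amino-acid frequencies are uniform for simplicity.
- **Proteomes** plant `round(rate·n)` features of each kind so
  zero-error mock predictor files reproduce planted fractions exactly:
  one 19-residue I/L/V/F segment per transmembrane protein (placed
  ≥ 40 residues in, away from the signal-peptide region), and a
  compliant M-KK-polar / hydrophobic-run / S-S-A N-terminus per Sec
  protein, with the h-region length (12 vs 9) splitting the strict and
  permissive regimes. Mock files flip truth with configurable
  false-positive/false-negative rates. The default spec replays the
  study genome's census: 1000 proteins at 29.6% / 3.4% / 9.0%.
- **Panels** draw genome signatures from a bivariate normal (default:
  300 genomes, mean (17% TM, ratio 1.1), variances 9.0 and 0.04 —
  a typical gram-negative background cloud centred well below the
  replayed genome's 29.6%) plus planted, flagged outlier rows.

All generators are pure functions of their spec including the seed;
reruns are byte-identical.

**What passing these tests shows — and does not.** Exact recovery on
synthetic families shows the screen's filtering, ranking and overhang
measurement are correct under the stated noise model; it does not show
that real homolog searches against a curated database would yield the
same gene list, which depends on database composition, e-value
culling and paralog structure that the simulator does not emulate
(no indels by default, no domain shuffling, no compositional bias).
Likewise the replayed census demonstrates the arithmetic and the
outlier geometry, not the behaviour of the real trained predictors.

## Numerical and reproducibility choices

- Coordinates are 1-based closed intervals throughout (BLAST/TMHMM
  convention).
- Hit ranking ties break lexicographically by subject id;
  reciprocal-best-hit ties likewise, with a warning emitted.
- Alignment traceback takes Biopython's first co-optimal alignment —
  deterministic across reruns.
- Filter idempotence: re-filtering a retained set returns it
  unchanged.
- Chi-square quantiles come from `scipy.stats.chi2`; the test suite
  cross-checks the 2-df closed form −2·ln(1−p).
- Monte-Carlo calibration at n = 10,000 puts the observed 95%-ellipse
  coverage within ±0.5 points of nominal and the 99.9% coverage within
  ±0.05 points.
- Every stochastic step takes an explicit seed; the analysis drivers
  and the acceptance script derive all child seeds from one top-level
  seed.

## Problem sizes

The shipped analyses use 50 families of 12 × ~200 aa for the screen
study, a 1000-protein census genome, a 300-genome reference panel and
10,000 Monte-Carlo draws for ellipse calibration — sizes at which every
result in this repository recomputes from scratch in well under a
minute on one core, while keeping binomial error on calibration
fractions small against the asserted bands.

## Known limitations

- The built-in signal-peptide/TM rules are intentionally naive; their
  false-positive profile on biological (non-uniform-composition)
  sequence differs from the trained predictors they stand in for.
- The screen assumes homolog hits are honest local alignments of a
  shared core; repeats or promiscuous domains can defeat the
  truncation guard.
- Single-linkage families inherit the usual chaining risk; for real
  paralog analyses a curated family map is preferable.
- The bivariate-normal panel model is as good as the panel: heavy
  tails or mixed groups inflate the covariance and hide outliers
  (the robust fit mitigates, but group structure should be declared
  explicitly).
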