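#!/usr/bin/env python
"""Census the replayed genome and classify it against the background panel.

Reads the mock predictor files of the replayed genome (planted at 29.6%
transmembrane proteins, 3.4%/9.0% Sec substrates), computes its
membrane signature, fits 95% and 99.9% confidence ellipses over the
300-genome background panel, and reports the Mahalanobis classification
and transmembrane-fraction percentile.

Writes results/signature_report.tsv and results/ellipse_background.tsv
(scatter/boundary data for plotting). Run after 01_simulate_inputs.py.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from atriscan.memsig import (  # noqa: E402
    GenomeSignature,
    classify_genome,
    ellipse_boundary,
    fit_reference_ellipse,
    genome_signature,
)
from atriscan.seq_io import (  # noqa: E402
    parse_sp_predictions,
    parse_tm_predictions,
    read_fasta,
)

ROOT = Path(__file__).resolve().parent.parent
DATA = ROOT / "scratch" / "data"


def main() -> None:
    proteome = read_fasta(DATA / "replayed.faa", genome_id="replayed")
    sig = genome_signature(
        proteome,
        parse_tm_predictions(DATA / "replayed.tmhmm.tsv"),
        parse_sp_predictions(DATA / "replayed.sp_v4like.tsv", "v4like"),
        parse_sp_predictions(DATA / "replayed.sp_v5like.tsv", "v5like"),
    )
    print(
        f"replayed genome: {sig.frac_tm_pct:.1f}% TM proteins, "
        f"{sig.frac_sec_v4_pct:.1f}%/{sig.frac_sec_v5_pct:.1f}% Sec substrates "
        f"(ratio {sig.sec_ratio:.3f})"
    )

    panel = pd.read_csv(DATA / "background_panel.tsv", sep="\t")
    background = [
        GenomeSignature(r.genome_id, r.frac_tm_pct, 1.0, r.sec_ratio)
        for r in panel.itertuples()
    ]
    model = fit_reference_ellipse(background)
    report = classify_genome(sig, model, background)
    print(
        f"Mahalanobis^2 = {report.mahalanobis_sq:.1f} vs chi-square(2) quantiles "
        f"{model.chi2_quantiles[0.95]:.3f} (95%) / {model.chi2_quantiles[0.999]:.3f} (99.9%)"
    )
    verdict = "outside" if not report.inside[0.999] else "inside"
    print(
        f"the replayed genome lies {verdict} the 99.9% ellipse and exceeds "
        f"{report.frac_tm_percentile:.1f}% of background genomes in TM fraction"
    )

    out = ROOT / "results" / "signature_report.tsv"
    pd.DataFrame(
        [
            {
                "genome_id": sig.genome_id,
                "frac_tm_pct": sig.frac_tm_pct,
                "frac_sec_v4_pct": sig.frac_sec_v4_pct,
                "frac_sec_v5_pct": sig.frac_sec_v5_pct,
                "sec_ratio": sig.sec_ratio,
                "mahalanobis_sq": report.mahalanobis_sq,
                "inside_95": report.inside[0.95],
                "inside_999": report.inside[0.999],
                "frac_tm_percentile": report.frac_tm_percentile,
            }
        ]
    ).to_csv(out, sep="\t", index=False)
    boundary = pd.DataFrame(
        [
            {"level": lv, "frac_tm_pct": x, "sec_ratio": y}
            for lv in (0.95, 0.999)
            for x, y in ellipse_boundary(model, lv)
        ]
    )
    boundary.to_csv(ROOT / "results" / "ellipse_background.tsv", sep="\t", index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
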