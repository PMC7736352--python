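#!/usr/bin/env python
"""Generate the synthetic study inputs.

Produces, under scratch/data/ (regenerable inputs; summary tables go to results/):
  - 50 homolog families (12 members, 200-aa core) with N-terminal
    extensions of 10-73 residues planted on member 0 — half noise-free,
    half with 5% core substitution;
  - one "replayed" census genome of 1000 proteins planted at the study
    rates (29.6% transmembrane, 3.4%/9.0% strict/permissive Sec), with
    zero-error mock predictor files;
  - a 300-genome background signature panel (bivariate normal around
    17% TM / ratio 1.1).

Run from the repository root:  python analysis/01_simulate_inputs.py
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

from atriscan.simulate import (  # noqa: E402
    FamilySpec,
    PanelSpec,
    ProteomeSpec,
    make_family,
    make_panel,
    make_proteome,
)

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "scratch" / "data"


def main() -> None:
    fam_dir = OUT / "families"
    fam_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(SEED)
    manifest = []
    for i in range(50):
        planted = int(rng.integers(10, 74))
        rate = 0.0 if i < 25 else 0.05
        spec = FamilySpec(
            seed=int(rng.integers(2**31)),
            substitution_rate=rate,
            nte_lengths={0: planted},
            nte_composition="amphipathic" if i % 5 == 0 else "random",
        )
        fam = make_family(spec, genome_id=f"family{i:02d}")
        fam.write(fam_dir / f"family{i:02d}.faa", fam_dir / f"family{i:02d}.truth.tsv")
        manifest.append(
            {"family": f"family{i:02d}", "planted_nte_len": planted,
             "substitution_rate": rate, "composition": spec.nte_composition,
             "seed": spec.seed}
        )
    pd.DataFrame(manifest).to_csv(fam_dir / "manifest.tsv", sep="\t", index=False)
    print(f"wrote 50 families to {fam_dir}")

    sim = make_proteome(ProteomeSpec(seed=SEED + 100), genome_id="replayed")
    paths = sim.write(OUT)
    print(f"wrote replayed census genome to {paths['fasta']}")

    panel = make_panel(PanelSpec(seed=SEED + 200, n_genomes=300))
    panel_path = OUT / "background_panel.tsv"
    panel.to_csv(panel_path, sep="\t", index=False)
    print(f"wrote {len(panel)}-genome background panel to {panel_path}")


if __name__ == "__main__":
    main()
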