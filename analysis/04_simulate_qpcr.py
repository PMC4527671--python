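"""Simulate the qPCR experiment with a planted ground truth.

Four reference candidates (two genuinely stable, two unstable — mirroring
the situation where two of four housekeeping genes prove too variable) plus
stress-response target genes with known log2 fold changes between control
and exposed groups.  Technical triplicates and per-gene efficiencies > 1.9
throughout.

Writes results/ct.csv and results/efficiencies.csv.
"""

from pathlib import Path

import pandas as pd

from radspan.io import write_ct_csv, write_efficiencies_csv
from radspan.simulate import GeneSimSpec, QpcrSimSpec, simulate_qpcr

SEED = 2015

GENES = {
    # candidates: RpL32/EF1alpha-like stable pair, Actin/betaTub-like unstable pair
    "RpL32": GeneSimSpec("reference", 2.00, 19.0),
    "EF1alpha": GeneSimSpec("reference", 1.97, 20.0),
    "Actin": GeneSimSpec("unstable", 2.02, 18.5),
    "betaTub": GeneSimSpec("unstable", 1.95, 21.0),
    # targets with planted per-group effects (log2 fold vs control)
    "Hsp70Aa": GeneSimSpec("target", 2.00, 24.0,
                           log2_fold_by_group={"irr20": 1.0, "irr40": 2.3}),
    "CG42751": GeneSimSpec("target", 1.98, 25.0,
                           log2_fold_by_group={"irr20": -2.0, "irr40": -0.5}),
    "mei41": GeneSimSpec("target", 2.01, 23.5,
                         log2_fold_by_group={"irr20": 0.3, "irr40": 0.2}),
}


def main() -> None:
    spec = QpcrSimSpec(genes=GENES, groups=("control", "irr20", "irr40"), seed=SEED)
    df = simulate_qpcr(spec)
    out = Path("results")
    out.mkdir(exist_ok=True)
    write_ct_csv(df, out / "ct.csv")
    eff = df.groupby("gene")["efficiency"].first()
    write_efficiencies_csv(eff, out / "efficiencies.csv")
    print(f"simulated {len(df)} reactions "
          f"({df['gene'].nunique()} genes x {df['sample_id'].nunique()} samples "
          f"x {df['tech_rep'].nunique()} technical replicates) -> {out}/ct.csv")


if __name__ == "__main__":
    main()
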