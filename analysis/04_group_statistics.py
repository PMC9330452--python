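#!/usr/bin/env python
"""Group statistics over the fitted relaxometry table.

Takes the tidy fits written by 03_fit_relaxometry.py, letters the
tissue effect per variable (normality-gated dispatch, compact letter
display), simulates a control-vs-drought long table at the printed
effect sizes to exercise the two-group branch, and runs a PCA of the
per-tuber MRI variables.  Outputs land under results/statistics/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from tuberelax import compare_many, compare_two, run_pca, simulate_long_table

ROOT = Path(__file__).resolve().parents[1] / "results"
OUT = ROOT / "statistics"


def tissue_letters(table: pd.DataFrame) -> pd.DataFrame:
    rows = {}
    for var in ("i0_rel_2", "t2_1", "t2_2"):
        sub = table[(table["variable"] == var) & table["value"].notna()]
        groups = {t: sub[sub["tissue"] == t]["value"].to_numpy()
                  for t in ("pith", "cortex", "flesh")}
        out = compare_many(groups, grouping_factor="tissue")
        rows[var] = out.letters
        print(f"tissue effect, {var:9s}: "
              + "  ".join(f"{c}={out.letters[c]}" for c in out.cells)
              + f"  ({out.test_used}, p = {out.p_value:.2e})")
    return pd.DataFrame(rows).T.rename_axis("variable")


def regime_letters() -> pd.DataFrame:
    """Control vs drought at the printed ~20 % slow-pool T2 decrease."""
    design = {}
    for tissue, (ctrl, sd) in (("cortex", (268.0, 4.0)), ("flesh", (268.0, 5.0)),
                               ("pith", (353.0, 15.0))):
        design[(tissue, 46, "control", "t2_2")] = (ctrl, sd)
        design[(tissue, 46, "SWD", "t2_2")] = (0.8 * ctrl, sd)
    table = simulate_long_table(design, n_per_cell=4, seed=21)
    rows = {}
    for tissue in ("pith", "cortex", "flesh"):
        sub = table[table["tissue"] == tissue]
        a = sub[sub["regime"] == "control"]["value"].to_numpy()
        b = sub[sub["regime"] == "SWD"]["value"].to_numpy()
        out = compare_two(a, b, grouping_factor="regime", names=("control", "SWD"))
        rows[tissue] = out.letters
        print(f"regime effect, t2_2, {tissue:7s}: control={out.letters['control']} "
              f"SWD={out.letters['SWD']} ({out.test_used}, p = {out.p_value:.3f})")
    return pd.DataFrame(rows).T.rename_axis("tissue")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    table = pd.read_csv(ROOT / "relaxometry" / "fits.csv")

    tissue_letters(table).to_csv(OUT / "letters_tissue.csv")
    regime_letters().to_csv(OUT / "letters_regime.csv")

    pca = run_pca(table, ["i0_rel_2", "t2_1", "t2_2"],
                  obs_keys=["sample_id", "tissue", "seed"])
    pca.scores.to_csv(OUT / "pca_scores.csv")
    pca.loadings.to_csv(OUT / "pca_loadings.csv")
    pd.DataFrame({"component": pca.scores.columns,
                  "explained_variance_pct": np.round(pca.explained_variance_pct, 2)}
                 ).to_csv(OUT / "pca_variance.csv", index=False)
    print("PCA explained variance (%): "
          + ", ".join(f"{v:.1f}" for v in pca.explained_variance_pct))
    print(f"wrote letter tables and PCA outputs to {OUT}")


if __name__ == "__main__":
    main()
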