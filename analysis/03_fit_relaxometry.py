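#!/usr/bin/env python
"""Fit every tissue ROI over four replicate acquisitions.

Re-runs the phantom -> segmentation -> fit chain for four seeds and
compares the mean recovered bi-exponential parameters with the
generative 32-DASE control values (slow-pool relative intensity and
both T2 values per tissue).  Writes the tidy fit table and the recovery
summary under results/relaxometry/.
"""

from pathlib import Path

import pandas as pd

from tuberelax import (default_phantom_spec, fit_all_tissues, generate_phantom,
                       segment_tissues)

OUT = Path(__file__).resolve().parents[1] / "results" / "relaxometry"
SEEDS = (1, 2, 3, 4)
GENERATIVE = {  # tissue -> (i0_rel_2 %, t2_1 ms, t2_2 ms)
    "cortex": (81.0, 64.0, 268.0),
    "flesh": (76.0, 61.0, 268.0),
    "pith": (88.0, 52.0, 353.0),
}


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    tables = []
    for seed in SEEDS:
        spec = default_phantom_spec(noise_sigma=2.0, seed=seed)
        img, _ = generate_phantom(spec)
        labels = segment_tissues(img)
        t = fit_all_tissues(img, labels)
        t["seed"] = seed
        tables.append(t)
    table = pd.concat(tables, ignore_index=True)
    table.to_csv(OUT / "fits.csv", index=False)

    piv = table.pivot_table(index="tissue", columns="variable", values="value")
    rows = []
    print(f"{'tissue':8s} {'variable':9s} {'recovered':>9s} {'generative':>10s}")
    for tissue, (i0, t1, t2) in GENERATIVE.items():
        for var, gen in (("i0_rel_2", i0), ("t2_1", t1), ("t2_2", t2)):
            got = piv.loc[tissue, var]
            rows.append({"tissue": tissue, "variable": var,
                         "recovered": round(got, 2), "generative": gen,
                         "error": round(got - gen, 2)})
            print(f"{tissue:8s} {var:9s} {got:9.2f} {gen:10.1f}")
    pd.DataFrame(rows).to_csv(OUT / "recovery.csv", index=False)
    n_sel = table[table["variable"] == "t2_2"]["value"].notna().sum()
    print(f"\n{n_sel} tissue fits over {len(SEEDS)} replicates; "
          f"wrote {OUT / 'fits.csv'} and {OUT / 'recovery.csv'}")


if __name__ == "__main__":
    main()
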