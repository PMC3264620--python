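#!/usr/bin/env python
"""Compare helix stability across the three analyzed systems.

Reads the report bundles written by 02_run_systems.py and quantifies
ligand stabilization the way the trajectory statistics are normally
summarized: class-frequency histograms (whole run and second half),
ratios of helical (class 1) and unwound (class 3) populations relative
to the ligand-free control, the fraction of frames with >= 5 alpha-HBs,
and per-class polar/nonpolar binding fractions for the two complexes.

Writes results/comparison.csv.
"""

from pathlib import Path

import pandas as pd

SYSTEMS = ["no_ligand", "dec_deta", "pep1b"]


def class_freqs(system: str, window: str) -> pd.Series:
    df = pd.read_csv(f"results/{system}/hist_rmsd.csv")
    sub = df[df.window == window].set_index("conf_class")["frequency"]
    return sub


def ahb5_freq(system: str, window: str) -> float:
    df = pd.read_csv(f"results/{system}/hist_ahb.csv")
    sub = df[(df.window == window) & (df.n_alpha_hb >= 5)]
    return float(sub["frequency"].sum())


def main() -> None:
    missing = [s for s in SYSTEMS
               if not Path(f"results/{s}/hist_rmsd.csv").is_file()]
    if missing:
        raise SystemExit(
            f"missing report bundles for {missing}; run "
            "analysis/02_run_systems.py first"
        )
    rows = []
    for window in ("whole", "second_half"):
        base = class_freqs("no_ligand", window)
        base_ahb5 = ahb5_freq("no_ligand", window)
        for system in SYSTEMS:
            f = class_freqs(system, window)
            rows.append({
                "system": system,
                "window": window,
                "freq_class1": f[1],
                "freq_class2": f[2],
                "freq_class3": f[3],
                "class1_vs_control": f[1] / base[1] if base[1] else float("inf"),
                "class3_vs_control": f[3] / base[3] if base[3] else float("inf"),
                "freq_ahb_ge5": ahb5_freq(system, window),
                "ahb_ge5_vs_control": (
                    ahb5_freq(system, window) / base_ahb5
                    if base_ahb5 else float("inf")
                ),
            })
    table = pd.DataFrame(rows)
    table.to_csv("results/comparison.csv", index=False)
    print(table.to_string(index=False,
                          float_format=lambda x: f"{x:.2f}"))

    print("\nper-class binding fractions (whole run):")
    for system in ("dec_deta", "pep1b"):
        stats = pd.read_csv(f"results/{system}/class_stats.csv")
        cols = ["conf_class", "fraction_polar", "fraction_nonpolar",
                "mean_ligand_hb", "mean_nonpolar"]
        print(f"-- {system}")
        print(stats[cols].to_string(index=False,
                                    float_format=lambda x: f"{x:.2f}"))


if __name__ == "__main__":
    main()
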