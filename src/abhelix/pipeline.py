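"""Configuration-driven end-to-end analysis runs.

``run_analysis`` takes a validated :class:`RunConfig`, loads or
generates trajectories, computes per-frame metrics (RMSD, Rg, alpha-HB
count, ligand HB and nonpolar-contact counts, conformation class,
binding flags), classifies endpoint groups, and emits the full report
set as CSV plus a JSON manifest.  Identical config and inputs give
byte-identical numeric outputs.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import abhelix
from abhelix import classify_stats as cs
from abhelix import contacts as ct
from abhelix import geometry as geo
from abhelix.model_io import (
    Frame,
    LigandSpec,
    Trajectory,
    load_ligand_spec,
    read_trajectory,
)
from abhelix.synthetic import SyntheticParams, simulate

__all__ = ["RunConfig", "run_analysis", "trajectory_metrics"]

log = logging.getLogger("abhelix")


@dataclass
class RunConfig:
    """Validated settings for one end-to-end analysis run.

    Either ``trajectories`` (paths to multi-model PDB files) or
    ``synthetic`` (keyword arguments for :class:`SyntheticParams`, plus
    ``n_trajectories``) must be given.  All criteria default to the
    standard protocol cutoffs: HB 2.4 A, residue-ligand contact 6.0 A,
    nonpolar contact 5.0 A, conformation-class thresholds 2.0/4.0 A.
    """

    output_dir: str
    trajectories: list[str] = field(default_factory=list)
    synthetic: dict | None = None
    ligand: str | None = None
    reference: str = "first-frame"
    analysis_start_ps: float = 0.0
    stride_ps: float = 10.0
    window_ns: float = 2.0
    hb_cutoff: float = ct.HB_CUTOFF
    contact_cutoff: float = ct.CONTACT_CUTOFF
    nonpolar_cutoff: float = ct.NONPOLAR_CUTOFF
    class_small: float = cs.CLASS_SMALL
    class_large: float = cs.CLASS_LARGE
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("hb_cutoff", "contact_cutoff", "nonpolar_cutoff",
                     "stride_ps", "window_ns"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0 < self.class_small < self.class_large):
            raise ValueError(
                "class thresholds must be strictly increasing and positive"
            )
        if not self.trajectories and self.synthetic is None:
            raise ValueError("config needs trajectories or synthetic block")
        if self.synthetic is not None and self.seed is None \
                and "seed" not in self.synthetic:
            raise ValueError("synthetic runs require an explicit seed")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh)
        return cls(**cfg)


def trajectory_metrics(traj: Trajectory,
                       ligand_spec: LigandSpec | None = None,
                       reference: Frame | None = None,
                       hb_cutoff: float = ct.HB_CUTOFF,
                       contact_cutoff: float = ct.CONTACT_CUTOFF,
                       nonpolar_cutoff: float = ct.NONPOLAR_CUTOFF,
                       class_small: float = cs.CLASS_SMALL,
                       class_large: float = cs.CLASS_LARGE) -> pd.DataFrame:
    """Per-frame metrics table for one trajectory.

    Every frame is first superposed on the reference (the trajectory's
    first frame unless an explicit reference is given) over all peptide
    heavy atoms; the RMSD is then measured over middle-region backbone
    atoms and the Rg over all middle-region atoms, mass-weighted.
    """
    traj = traj.analyzable()
    topo = traj.topology
    if reference is None:
        reference = traj.frames[0]
    fit_sel = geo.fit_selection_default()
    meas_sel = geo.measure_selection_default(topo.region_mid)
    rg_sel = geo.rg_selection_default(topo.region_mid)
    has_lig = topo.has_ligand and ligand_spec is not None
    rows = []
    for fr in traj.frames:
        _, fitted = geo.superpose(fr, reference, topo, fit_sel)
        r = geo.rmsd(fitted, reference, topo, meas_sel)
        rg = geo.radius_of_gyration(fitted, topo, rg_sel)
        n_ahb = ct.count_alpha_hbs(fitted, topo, topo.region_mid, hb_cutoff)
        if has_lig:
            hbs = ct.ligand_peptide_hbonds(fitted, topo, hb_cutoff)
            n_hb = len(hbs)
            n_np = ct.nonpolar_contacts(fitted, topo, ligand_spec,
                                        nonpolar_cutoff)
            dual = ct.dual_mode_binding(hbs, topo, ligand_spec)
        else:
            n_hb, n_np, dual = 0, 0, False
        rows.append({
            "time_ps": fr.time_ps,
            "rmsd_mid": r,
            "rg_mid": rg,
            "n_alpha_hb": n_ahb,
            "n_ligand_hb": n_hb,
            "n_nonpolar": n_np,
            "conf_class": cs.classify_frame(r, class_small, class_large),
            "polar_bound": n_hb >= 1,
            "nonpolar_bound": n_np >= 1,
            "dual_bound": dual,
        })
    return pd.DataFrame(rows, columns=cs.FRAME_METRIC_COLUMNS)


def _load_inputs(config: RunConfig):
    spec = load_ligand_spec(config.ligand) if config.ligand else None
    trajs: list[Trajectory] = []
    if config.trajectories:
        for p in config.trajectories:
            if not Path(p).is_file():
                raise FileNotFoundError(f"cannot read trajectory file {p}")
            log.info("reading trajectory %s", p)
            trajs.append(read_trajectory(
                p, "pdb", ligand_spec=spec, stride_ps=config.stride_ps,
                analysis_start_ps=config.analysis_start_ps,
            ))
    else:
        syn = dict(config.synthetic)
        n_traj = int(syn.pop("n_trajectories", 1))
        base_seed = int(syn.pop("seed", config.seed))
        if spec is not None:
            syn.setdefault("ligand_spec", config.ligand)
        for k in range(n_traj):
            params = SyntheticParams(seed=base_seed + k, **syn)
            log.info("simulating trajectory %d/%d (seed %d)",
                     k + 1, n_traj, params.seed)
            traj, _ = simulate(params)
            traj.analysis_start_ps = config.analysis_start_ps
            trajs.append(traj)
    return trajs, spec


def _reference_frame(config: RunConfig, traj: Trajectory) -> Frame | None:
    if config.reference == "first-frame":
        return None
    ref_traj = read_trajectory(
        config.reference, "pdb",
        ligand_spec=config.ligand,
        stride_ps=config.stride_ps,
    )
    return ref_traj.frames[0]


def run_analysis(config: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns a dict with the in-memory results (metrics tables, summary,
    class stats, histograms, contact map).  On any failure the partial
    output directory is removed.
    """
    outdir = Path(config.output_dir)
    created = not outdir.exists()
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        return _run_analysis_inner(config, outdir)
    except Exception:
        if created:
            shutil.rmtree(outdir, ignore_errors=True)
        else:
            for f in outdir.glob("*.csv"):
                f.unlink()
            (outdir / "manifest.json").unlink(missing_ok=True)
        raise


def _run_analysis_inner(config: RunConfig, outdir: Path) -> dict:
    trajs, spec = _load_inputs(config)
    metrics_list = []
    summaries = []
    for k, traj in enumerate(trajs):
        ref = _reference_frame(config, traj)
        m = trajectory_metrics(
            traj, spec, ref,
            config.hb_cutoff, config.contact_cutoff, config.nonpolar_cutoff,
            config.class_small, config.class_large,
        )
        log.info("trajectory %d: %d frames analyzed", k + 1, len(m))
        m.to_csv(outdir / f"frame_metrics_{k + 1:02d}.csv", index=False)
        metrics_list.append(m)
        s = cs.summarize_trajectory(m, config.window_ns)
        summaries.append({
            "trajectory": k + 1,
            "avg_rmsd": s.avg_rmsd_last,
            "avg_ahb": s.avg_ahb_last,
            "group": s.group,
            "ahb_consistent": s.consistent,
        })

    summary = pd.DataFrame(summaries)
    mean_rmsd, sd_rmsd = cs.column_summary(summary["avg_rmsd"])
    mean_ahb, sd_ahb = cs.column_summary(summary["avg_ahb"])
    summary.to_csv(outdir / "summary.csv", index=False)

    hist = pd.DataFrame({
        "window": ["whole"] * 3 + ["second_half"] * 3,
        "conf_class": [1, 2, 3] * 2,
        "frequency": np.concatenate([
            cs.histogram_rmsd(metrics_list, "whole"),
            cs.histogram_rmsd(metrics_list, "second_half"),
        ]),
    })
    hist.to_csv(outdir / "hist_rmsd.csv", index=False)
    hist_ahb = pd.DataFrame({
        "window": ["whole"] * 7 + ["second_half"] * 7,
        "n_alpha_hb": list(range(7)) * 2,
        "frequency": np.concatenate([
            cs.histogram_ahb(metrics_list, "whole"),
            cs.histogram_ahb(metrics_list, "second_half"),
        ]),
    })
    hist_ahb.to_csv(outdir / "hist_ahb.csv", index=False)

    result = {
        "metrics": metrics_list,
        "summary": summary,
        "column_means": {"rmsd": mean_rmsd, "ahb": mean_ahb},
        "column_sds": {"rmsd": sd_rmsd, "ahb": sd_ahb},
        "hist_rmsd": hist,
        "hist_ahb": hist_ahb,
    }

    if spec is not None:
        stats = cs.class_contact_stats(metrics_list)
        stats_df = pd.DataFrame({
            "conf_class": [1, 2, 3],
            "fraction_polar": [stats.fraction_polar[c] for c in (1, 2, 3)],
            "fraction_nonpolar": [
                stats.fraction_nonpolar[c] for c in (1, 2, 3)
            ],
            "mean_ligand_hb": [stats.mean_hb[c] for c in (1, 2, 3)],
            "sd_ligand_hb": [stats.sd_hb[c] for c in (1, 2, 3)],
            "mean_nonpolar": [stats.mean_nonpolar[c] for c in (1, 2, 3)],
            "sd_nonpolar": [stats.sd_nonpolar[c] for c in (1, 2, 3)],
            "n_frames": [stats.class_frames[c] for c in (1, 2, 3)],
        })
        stats_df.to_csv(outdir / "class_stats.csv", index=False)
        cmaps = [ct.contact_map(t, spec, config.contact_cutoff)
                 for t in trajs]
        cmap = sum(c * len(m) for c, m in zip(cmaps, metrics_list)) \
            / sum(len(m) for m in metrics_list)
        cmap.to_csv(outdir / "contact_map.csv")
        timelines = []
        for k, m in enumerate(metrics_list):
            tl = cs.binding_timeline(m)
            tl.insert(0, "trajectory", k + 1)
            tl["classes"] = tl["classes"].map(
                lambda cc: " ".join(str(x) for x in cc)
            )
            timelines.append(tl)
        pd.concat(timelines, ignore_index=True).to_csv(
            outdir / "timelines.csv", index=False
        )
        result["class_stats"] = stats_df
        result["contact_map"] = cmap

    manifest = {
        "abhelix_version": abhelix.__version__,
        "config": {k: v for k, v in asdict(config).items()},
        "n_trajectories": len(trajs),
        "frames_per_trajectory": [len(m) for m in metrics_list],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("report bundle written to %s", outdir)
    return result
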