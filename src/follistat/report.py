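"""Pipeline orchestration: synthetic (or pre-segmented) data -> statistics.

Runs the full experiment the package exists for: simulate groups of
follicles (a zoned germinal-center group and an unzoned follicular-lymphoma
group by default), optionally render/denoise/segment images, compute
per-compartment densities with pairwise Welch tests, estimate g(r) per
follicle, pool min/median/max envelopes per group, classify each follicle
against its Monte-Carlo CSR envelope, and write everything to CSV/JSON plus
figures.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import PointPattern, RegionMask, SpatialCurve
from .preprocess import DenoiseParams, tv_poisson_denoise
from .segment import SegmentParams, score_membrane, segment_nuclei, to_point_pattern
from .spatial import (
    classify_pattern,
    compare_densities,
    csr_envelope,
    density,
    default_r_grid,
    pair_correlation,
    pooled_envelope,
)
from .synthetic import ProcessSpec, RenderSpec, make_follicle_window, render_image, simulate_points

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "demo_config", "run_pipeline", "plot_results"]


@dataclasses.dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``panel`` maps cell-type labels to marker kind (``nuclear`` or
    ``membrane``); ``groups`` maps a group name to its layout: whether the
    follicles are zoned (LZ/DZ) or analyzed whole, how many specimens and
    follicles per specimen, the follicle size, and one process spec (as a
    kwargs dict, without seed) per cell type in the panel. ``seed`` drives
    every stochastic stage through a seed tree, so a config + seed pair
    reproduces a run bit-identically.
    """

    outdir: str = "follistat_run"
    seed: int = 0
    panel: dict = dataclasses.field(default_factory=dict)
    groups: dict = dataclasses.field(default_factory=dict)
    render: bool = False
    render_params: dict = dataclasses.field(default_factory=dict)
    denoise: bool = False
    denoise_params: dict = dataclasses.field(default_factory=dict)
    segment_params: dict = dataclasses.field(default_factory=dict)
    r_max: float = 60.0
    r_step: float = 1.0
    r_band: tuple = (2.0, 20.0)
    n_sim: int = 99
    rank: int = 3
    pixel_size: float = 0.74

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["r_band"] = list(d["r_band"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "r_band" in d:
            d["r_band"] = tuple(d["r_band"])
        return cls(**d)


def demo_config(outdir: str = "follistat_demo", seed: int = 0, render: bool = False) -> RunConfig:
    """The gc-vs-fl demonstration experiment.

    Nine zoned germinal-center follicles (3 specimens x 3 follicles) with
    CSR-arranged B and T cells, against nine unzoned lymphoma follicles
    where T cells follow a Thomas cluster process with a 5 um offspring
    dispersal — the scale at which clustering is expected to show in g(r).
    """
    t_csr = {"kind": "csr", "intensity": 600.0}
    t_thomas = {
        "kind": "thomas",
        "thomas_parent_intensity": 120.0,
        "thomas_mean_offspring": 5.0,
        "thomas_sigma": 5.0,
    }
    b_csr = {"kind": "csr", "intensity": 1500.0}
    return RunConfig(
        outdir=outdir,
        seed=seed,
        render=render,
        panel={"B": "nuclear", "CD3": "membrane"},
        groups={
            "GC": {
                "zoned": True,
                "n_specimens": 3,
                "n_follicles": 3,
                "width_um": 400.0,
                "height_um": 400.0,
                "lz_fraction": 0.5,
                "processes": {"B": b_csr, "CD3": t_csr},
            },
            "FL": {
                "zoned": False,
                "n_specimens": 3,
                "n_follicles": 3,
                "width_um": 400.0,
                "height_um": 400.0,
                "processes": {"B": b_csr, "CD3": t_thomas},
            },
        },
    )


def _follicle_windows(group_cfg: dict, pixel_size: float):
    gc, lz, dz = make_follicle_window(
        group_cfg["width_um"],
        group_cfg["height_um"],
        group_cfg.get("lz_fraction", 0.5),
        pixel_size,
    )
    if group_cfg.get("zoned", False):
        return gc, {"LZ": lz, "DZ": dz}
    fl = RegionMask(gc.mask, pixel_size, "FL")
    return fl, {"FL": fl}


def _segment_follicle(cfg: RunConfig, gts: dict, window: RegionMask, seed_seq) -> dict:
    """Render -> (denoise) -> segment one follicle; return points per type."""
    rseeds = seed_seq.spawn(len(cfg.panel) + 1)
    rkw = dict(cfg.render_params)
    rkw.setdefault("pixel_size", cfg.pixel_size)
    seg_params = SegmentParams(**cfg.segment_params)
    den_params = DenoiseParams(**cfg.denoise_params)

    # DAPI: nuclei of every simulated cell
    from .datatypes import GroundTruth

    all_pts = np.concatenate([gt.points for gt in gts.values()]) if gts else np.zeros((0, 2))
    dapi_gt = GroundTruth(all_pts, "DAPI", None, window)
    dapi = render_image(
        dapi_gt, RenderSpec(**rkw, seed=int(rseeds[0].generate_state(1)[0] % 2**31)),
        marker_kind="nuclear", channel="DAPI",
    )
    if cfg.denoise:
        dapi = tv_poisson_denoise(dapi, den_params)
    dapi_nuclei = segment_nuclei(dapi, seg_params, cell_type="DAPI")

    out = {}
    for k, (label, kind) in enumerate(cfg.panel.items()):
        seed = int(rseeds[k + 1].generate_state(1)[0] % 2**31)
        chan = render_image(
            gts[label], RenderSpec(**rkw, seed=seed), marker_kind=kind, channel=label
        )
        if cfg.denoise:
            chan = tv_poisson_denoise(chan, den_params)
        if kind == "nuclear":
            dets = segment_nuclei(chan, seg_params, cell_type=label)
        else:
            dets = score_membrane(chan, dapi_nuclei, seg_params, cell_type=label)
        out[label] = dets
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the configured experiment and write its outputs.

    Returns a report dict with the density table, pairwise Welch tests,
    per-(group, compartment, cell type) curves (per-follicle g, pooled
    envelope, CSR envelope of the first follicle, per-follicle calls and
    the majority call) and the path of the JSON manifest.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    r_grid = default_r_grid(cfg.r_max, cfg.r_step)
    root = np.random.SeedSequence(cfg.seed)
    timings: dict[str, float] = {}
    warnings_seen: list[str] = []

    dens_rows = []
    curves: dict[tuple, dict] = {}
    t0 = time.perf_counter()
    for gi, (gname, gcfg) in enumerate(cfg.groups.items()):
        gseq = np.random.SeedSequence((cfg.seed, gi))
        follicle_idx = 0
        for s in range(gcfg.get("n_specimens", 3)):
            for f in range(gcfg.get("n_follicles", 3)):
                fseq = np.random.SeedSequence((cfg.seed, gi, s, f))
                child = fseq.spawn(len(cfg.panel) + 1)
                window, comps = _follicle_windows(gcfg, cfg.pixel_size)
                gts = {}
                pps = {}
                for k, label in enumerate(cfg.panel):
                    pkw = dict(gcfg["processes"][label])
                    pkw["seed"] = int(child[k].generate_state(1)[0] % 2**31)
                    spec = ProcessSpec(**pkw)
                    pp, gt = simulate_points(spec, window)
                    gts[label] = gt
                    pps[label] = pp
                if cfg.render:
                    dets = _segment_follicle(cfg, gts, window, child[-1])
                    pps = {
                        label: to_point_pattern(d, window, cell_type=label)
                        for label, d in dets.items()
                    }
                # whole-window densities plus zone-wise stats; g(r) is only
                # estimated in compartments that look homogeneous (LZ/DZ/FL)
                density_comps = {window.label: window, **comps}
                for cname, cmask in density_comps.items():
                    curve_comp = cname in comps
                    for label, pp in pps.items():
                        sub = PointPattern(
                            pp.points[cmask.contains(pp.points)], cmask, label
                        )
                        dens_rows.append(
                            {
                                "group": gname,
                                "specimen": s,
                                "follicle": follicle_idx,
                                "compartment": cname,
                                "cell_type": label,
                                "n": sub.n,
                                "density_per_mm2": density(sub),
                            }
                        )
                        if not curve_comp:
                            continue
                        key = (gname, cname, label)
                        entry = curves.setdefault(
                            key, {"per_follicle": [], "calls": [], "csr_env": None}
                        )
                        if sub.n >= 2:
                            curve = pair_correlation(sub, r_grid)
                            label_idx = list(cfg.panel).index(label)
                            env_seed = int(
                                np.random.SeedSequence(
                                    (cfg.seed, gi, s, f, label_idx)
                                ).generate_state(1)[0]
                                % 2**31
                            )
                            env = csr_envelope(
                                sub, cfg.n_sim, cfg.rank, r_grid, seed=env_seed
                            )
                            call, radii = classify_pattern(curve, env, cfg.r_band)
                            entry["per_follicle"].append(curve)
                            entry["calls"].append(call)
                            if entry["csr_env"] is None:
                                entry["csr_env"] = env
                        else:
                            log.warning(
                                "%s/%s/%s follicle %d: too few points for g(r)",
                                gname, cname, label, follicle_idx,
                            )
                follicle_idx += 1
    timings["simulate_and_stats_s"] = time.perf_counter() - t0

    densities = pd.DataFrame(dens_rows)
    densities.to_csv(outdir / "densities.csv", index=False, float_format="%.6f")

    # pairwise Welch tests between compartments, per cell type
    test_rows = []
    if len(densities):
        comps_all = densities[["group", "compartment"]].drop_duplicates()
        pairs = [
            (a, b)
            for i, a in enumerate(comps_all.itertuples(index=False))
            for b in list(comps_all.itertuples(index=False))[i + 1 :]
        ]
        for label in cfg.panel:
            for a, b in pairs:
                da = densities.query(
                    "group == @a.group and compartment == @a.compartment and cell_type == @label"
                )["density_per_mm2"]
                db = densities.query(
                    "group == @b.group and compartment == @b.compartment and cell_type == @label"
                )["density_per_mm2"]
                if len(da) < 2 or len(db) < 2:
                    continue
                t, p, ma, mb = compare_densities(da, db)
                test_rows.append(
                    {
                        "cell_type": label,
                        "compartment_a": f"{a.group}:{a.compartment}",
                        "compartment_b": f"{b.group}:{b.compartment}",
                        "t": t,
                        "p": p,
                        "mean_a": ma,
                        "mean_b": mb,
                    }
                )
    tests = pd.DataFrame(test_rows)
    tests.to_csv(outdir / "density_tests.csv", index=False, float_format="%.6f")

    # pooled envelopes + classification table
    from .io import write_curve

    (outdir / "curves").mkdir(exist_ok=True)
    call_rows = []
    for (gname, cname, label), entry in curves.items():
        pf = entry["per_follicle"]
        if len(pf) >= 2:
            entry["pooled"] = pooled_envelope(pf)
            write_curve(entry["pooled"], outdir / "curves" / f"{label}_{gname}_{cname}.csv")
        elif len(pf) == 1:
            entry["pooled"] = pf[0]
            write_curve(pf[0], outdir / "curves" / f"{label}_{gname}_{cname}.csv")
        if entry["calls"]:
            vals, counts = np.unique(entry["calls"], return_counts=True)
            entry["majority_call"] = str(vals[np.argmax(counts)])
            for i, c in enumerate(entry["calls"]):
                call_rows.append(
                    {
                        "group": gname,
                        "compartment": cname,
                        "cell_type": label,
                        "follicle": i,
                        "call": c,
                    }
                )
            call_rows.append(
                {
                    "group": gname,
                    "compartment": cname,
                    "cell_type": label,
                    "follicle": -1,
                    "call": entry["majority_call"],
                }
            )
    pd.DataFrame(call_rows).to_csv(outdir / "classification.csv", index=False)

    manifest = {
        "package": "follistat",
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "numpy_version": np.__version__,
        "timings": timings,
        "warnings": warnings_seen,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return {
        "outdir": str(outdir),
        "densities": densities,
        "tests": tests,
        "curves": curves,
        "manifest_path": str(outdir / "manifest.json"),
    }


def plot_results(report: dict) -> list[Path]:
    """Figures for a completed run: one g(r) panel per (cell type, group,
    compartment) with the grey min/max envelope and thick median line, plus
    one density strip/box figure per cell type."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(report["outdir"]) / "figures"
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    for (gname, cname, label), entry in report["curves"].items():
        pooled: SpatialCurve | None = entry.get("pooled")
        fig, ax = plt.subplots(figsize=(4, 3))
        if pooled is None:
            log.warning("no curve for %s/%s/%s; empty panel", gname, cname, label)
            ax.text(0.5, 0.5, "no data", ha="center", va="center", transform=ax.transAxes)
        else:
            if pooled.lo is not None and pooled.hi is not None:
                ax.fill_between(pooled.r, pooled.lo, pooled.hi, color="0.8", label="min-max")
            med = pooled.med if pooled.med is not None else pooled.g
            ax.plot(pooled.r, med, "k-", lw=2, label="median")
            ax.axhline(1.0, color="0.4", ls=":")
        ax.set_xlabel("distance r (μm)")
        ax.set_ylabel("g(r)")
        call = entry.get("majority_call", "")
        ax.set_title(f"{label} in {gname}:{cname}" + (f" [{call}]" if call else ""))
        fig.tight_layout()
        path = outdir / f"g_{label}_{gname}_{cname}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        files.append(path)

    densities: pd.DataFrame = report["densities"]
    if len(densities):
        for label, sub in densities.groupby("cell_type"):
            fig, ax = plt.subplots(figsize=(4, 3))
            keys = sub.groupby(["group", "compartment"])
            names, vals = zip(*[(f"{g}:{c}", v["density_per_mm2"].to_numpy()) for (g, c), v in keys])
            ax.boxplot(vals, tick_labels=names)
            for i, v in enumerate(vals, start=1):
                ax.plot(np.full(len(v), i), v, "o", ms=3, alpha=0.6)
            ax.set_ylabel("cells per mm$^2$")
            ax.set_title(str(label))
            fig.tight_layout()
            path = outdir / f"density_{label}.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            files.append(path)
    return files
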