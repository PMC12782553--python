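"""Named end-to-end experiments and figure regeneration.

Each experiment reads nothing but its manifest, writes tidy CSV tables plus a
JSON summary into the output directory, and logs the resolved configuration.
Figure commands consume only files previously written by an experiment.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .analysis import (
    calibrate_site_distance,
    code_projection,
    correlation_profile,
    visit_correlation_curve,
)
from .config import ModelConfig
from .io import ExperimentManifest
from .memory import BarcodeMemory
from .tasks import (
    TaskSpec,
    correct_reject_sweep,
    default_factory,
    make_ablation,
    run_three_cache_task,
    single_cache_width,
)
from .variants import (
    feedforward_barcode,
    hybrid_factory,
    init_feedforward,
    make_model,
)

log = logging.getLogger("barcodenet")

EXPERIMENTS = (
    "regimes",
    "calibration",
    "profile",
    "task",
    "ablations",
    "projection",
    "recall_skew",
    "feedforward",
)


def run_experiment(manifest: ExperimentManifest) -> Dict:
    """Dispatch one named experiment; returns its summary dict."""
    manifest.write()
    cfg = manifest.config
    log.info("experiment=%s seed=%d config=%s", manifest.experiment,
             manifest.master_seed, cfg.to_dict())
    outdir = Path(manifest.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fn = {
        "regimes": _exp_regimes,
        "calibration": _exp_calibration,
        "profile": _exp_profile,
        "task": _exp_task,
        "ablations": _exp_ablations,
        "projection": _exp_projection,
        "recall_skew": _exp_recall_skew,
        "feedforward": _exp_feedforward,
    }.get(manifest.experiment)
    if fn is None:
        raise ValueError(
            f"unknown experiment {manifest.experiment!r}; valid: {EXPERIMENTS}"
        )
    summary = fn(cfg, manifest.master_seed, outdir, manifest.params)
    (outdir / f"summary_{manifest.experiment}.json").write_text(
        json.dumps(summary, indent=2, default=float)
    )
    return summary


# --------------------------------------------------------------------------

def _exp_regimes(cfg: ModelConfig, seed: int, outdir: Path, params: dict) -> Dict:
    """Correlation-vs-separation profiles at several weight-fluctuation scales."""
    sigmas = params.get("sigmas", (1.0, 7.0, 20.0))
    n_seeds = int(params.get("n_seeds", 5))
    max_sep = cfg.N_s // 2
    rows = []
    for sig in sigmas:
        c = cfg.replace(sigma=float(sig))
        for rep in range(n_seeds):
            model = BarcodeMemory(c, seed=seed + rep)
            X = model.gain_activity(np.arange(c.N_s), 1.0)
            C = np.corrcoef(X.T)
            for d in range(max_sep + 1):
                val = float(np.mean([C[k, (k + d) % c.N_s] for k in range(c.N_s)]))
                rows.append((float(sig), rep, d, val))
            del model
    df = pd.DataFrame(rows, columns=["sigma", "rep", "separation", "correlation"])
    df.to_csv(outdir / "regimes.csv", index=False)
    adj = df[df.separation == 1].groupby("sigma")["correlation"].mean()
    return {"adjacent_correlation": adj.to_dict()}


def _exp_calibration(cfg: ModelConfig, seed: int, outdir: Path, params: dict) -> Dict:
    curve = visit_correlation_curve(cfg, seed=seed)
    pd.DataFrame(
        {"separation": np.arange(len(curve)), "normalized_correlation": curve}
    ).to_csv(outdir / "calibration.csv", index=False)
    site = calibrate_site_distance(curve, target=float(params.get("target", 0.75)))
    return {
        "correlation_at_8": float(curve[8]) if len(curve) > 8 else None,
        "site_distance_states": site,
    }


def _exp_profile(cfg: ModelConfig, seed: int, outdir: Path, params: dict) -> Dict:
    prof = correlation_profile(
        cfg,
        n_experiments=int(params.get("n_experiments", 20)),
        n_sites=int(params.get("n_sites", 5)),
        master_seed=seed,
    )
    prof.table.to_csv(outdir / "profile.csv", index=False)
    same_cr = prof.value("cache-retrieval", 0.0)
    return {"cache_retrieval_same_site": same_cr, "normalization": prof.normalization}


def _exp_task(cfg: ModelConfig, seed: int, outdir: Path, params: dict) -> Dict:
    variant = params.get("variant", "default")
    factory = (lambda c, s: make_model(c, s, variant)) if variant != "default" else default_factory
    spec = TaskSpec(
        n_seeds=int(params.get("n_seeds", 35)),
        stages=params.get("stages", "final"),
    )
    res = run_three_cache_task(spec, cfg, factory=factory, master_seed=seed)
    res.table.to_csv(outdir / f"task_{variant}.csv", index=False)
    cr = correct_reject_sweep(
        cfg, spacings=params.get("spacings", (8, 16, 24)),
        n_seeds=spec.n_seeds, factory=factory, master_seed=seed,
    )
    cr.to_csv(outdir / f"correct_reject_{variant}.csv", index=False)
    width = single_cache_width(cfg, n_seeds=min(spec.n_seeds, 10),
                               factory=factory, master_seed=seed)
    width.to_csv(outdir / f"width_{variant}.csv", index=False)
    succ0 = res.success_curve(0.0)
    return {
        "success_at_cache_s0": float(
            succ0.loc[succ0.dist_nearest == 0, "p"].iloc[0]
        ),
        "midpoint_correct_reject_8": float(
            cr[(cr.spacing == 8) & np.isclose(cr.s, 0.0)]["p_correct_reject"].iloc[0]
        ),
        "mean_width": float((width.left + width.right).mean() / 2.0),
    }


def _exp_ablations(cfg: ModelConfig, seed: int, outdir: Path, params: dict) -> Dict:
    out = {}
    for kind in ("full", "place_only", "barcode_only"):
        factory = make_ablation(kind, cfg)
        spec = TaskSpec(n_seeds=int(params.get("n_seeds", 20)))
        res = run_three_cache_task(spec, cfg, factory=factory, master_seed=seed)
        res.table.to_csv(outdir / f"task_{kind}.csv", index=False)
        cr = correct_reject_sweep(
            cfg, spacings=(8, 16), n_seeds=spec.n_seeds,
            factory=factory, master_seed=seed, s_values=(0.0,),
        )
        cr.to_csv(outdir / f"correct_reject_{kind}.csv", index=False)
        out[kind] = {
            "midpoint_cr_8": float(cr[cr.spacing == 8]["p_correct_reject"].iloc[0]),
            "success_d0_s04": _succ_at(res, 0.4, 0),
        }
    return out


def _succ_at(res, s, d):
    c = res.success_curve(s)
    sel = c[c.dist_nearest == d]
    return float(sel["p"].iloc[0]) if len(sel) else None


def _exp_projection(cfg: ModelConfig, seed: int, outdir: Path, params: dict) -> Dict:
    model = make_model(cfg, seed, "hybrid")
    r_sweep = params.get("r_sweep", np.round(np.arange(0, 1.01, 0.1), 2))
    dec = code_projection(
        model, r_sweep,
        predictive_offset_states=int(params.get("predictive_offset_states", 1)),
    )
    dec.to_frame().to_csv(outdir / "projection.csv", index=False)
    return {
        "place_argmax_r": float(dec.r_values[int(np.argmax(dec.place))]),
        "predictive_peak_r": dec.predictive_peak_r,
        "barcode_peak_r": dec.barcode_peak_r,
    }


def _exp_recall_skew(cfg: ModelConfig, seed: int, outdir: Path, params: dict) -> Dict:
    """Single-cache seed-output profile for hybrid vs default model."""
    n_seeds = int(params.get("n_seeds", 5))
    rows = []
    for variant in ("default", "hybrid"):
        for rep in range(n_seeds):
            model = make_model(cfg, seed + rep, variant)
            c = cfg.N_s // 2
            model.store_cache(c)
            _, y_seed, _ = model.recall_event(np.arange(cfg.N_s), s_strength=0.0)
            for st in range(cfg.N_s):
                rows.append((variant, rep, st, float(y_seed[st])))
            del model
    df = pd.DataFrame(rows, columns=["variant", "rep", "state", "y_seed"])
    df.to_csv(outdir / "recall_skew.csv", index=False)
    return _skew_summary(df, cfg)


def _skew_summary(df: pd.DataFrame, cfg: ModelConfig) -> Dict:
    out = {}
    c = cfg.N_s // 2
    for variant, sub in df.groupby("variant"):
        mean = sub.groupby("state")["y_seed"].mean().to_numpy()
        above = mean > cfg.kappa
        approach = past = 0
        for d in range(1, cfg.N_s // 2):  # approach side: states before c (clockwise walk)
            if above[(c - d) % cfg.N_s]:
                approach += 1
            else:
                break
        for d in range(1, cfg.N_s // 2):
            if above[(c + d) % cfg.N_s]:
                past += 1
            else:
                break
        out[variant] = {"approach_extent": approach, "past_extent": past}
    return out


def _exp_feedforward(cfg: ModelConfig, seed: int, outdir: Path, params: dict) -> Dict:
    """Adjacent-state decorrelation of feedforward barcodes vs hidden sparsity."""
    from .config import RandomStreams
    from .network import build_place_inputs

    thetas = params.get("thetas", (1.0, 0.5, 0.1, 0.02, 0.005))
    target = float(params.get("target_sparsity", 0.1))
    streams = RandomStreams(seed)
    bank = build_place_inputs(cfg)
    rows = []
    for th in thetas:
        ff = init_feedforward(cfg.replace(theta=float(th)), streams["feedforward"])
        X = feedforward_barcode(bank, ff, target_sparsity=target)
        C = np.corrcoef(X)
        adj = float(np.mean(np.diag(C, 1)))
        rows.append((float(th), adj))
    df = pd.DataFrame(rows, columns=["theta", "adjacent_correlation"])
    df.to_csv(outdir / "feedforward.csv", index=False)
    return {"adjacent_correlation": dict(zip(df.theta, df.adjacent_correlation))}


# --------------------------------------------------------------------------
# figures
# --------------------------------------------------------------------------

def regenerate_figures(outdir: str | Path) -> list:
    """Render vector figures from experiment tables present in ``outdir``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    made = []

    def _save(fig, name):
        p = outdir / f"{name}.svg"
        fig.savefig(p, bbox_inches="tight")
        plt.close(fig)
        made.append(p)

    reg = outdir / "regimes.csv"
    if reg.exists():
        df = pd.read_csv(reg)
        fig, axes = plt.subplots(1, df.sigma.nunique(), figsize=(9, 2.6), sharey=True)
        for ax, (sig, sub) in zip(np.atleast_1d(axes), df.groupby("sigma")):
            m = sub.groupby("separation")["correlation"].mean()
            ax.plot(m.index, m.values, "k-")
            ax.set_title(f"sigma={sig:g}")
            ax.set_xlabel("separation (states)")
        _save(fig, "fig2B")

    prof = outdir / "profile.csv"
    if prof.exists():
        df = pd.read_csv(prof)
        fig, ax = plt.subplots(figsize=(4, 3))
        for cond, sub in df.groupby("condition"):
            sub = sub.sort_values("distance")
            ax.errorbar(sub.distance, sub.value, yerr=2.58 * sub["sem"], label=cond)
        ax.set_xlabel("site distance")
        ax.set_ylabel("normalized correlation")
        ax.legend()
        _save(fig, "fig3D")

    cr = outdir / "correct_reject_default.csv"
    if cr.exists():
        df = pd.read_csv(cr)
        fig, ax = plt.subplots(figsize=(4, 3))
        for s, sub in df.groupby("s"):
            ax.plot(sub.dist_to_flank / 8.0, sub.p_correct_reject, "-o", label=f"s={s:g}")
        ax.set_xlabel("distance to flanking caches (site distances)")
        ax.set_ylabel("P(correct reject)")
        ax.legend()
        _save(fig, "fig4EF")

    for name, stem in (("fig5CD", "task_place_only"), ("fig6F", "projection"),
                       ("fig6G", "recall_skew")):
        p = outdir / f"{stem}.csv"
        if not p.exists():
            continue
        df = pd.read_csv(p)
        fig, ax = plt.subplots(figsize=(4, 3))
        if stem == "projection":
            for col in ("place", "predictive", "barcode"):
                ax.plot(df.r, df[col], label=col)
            ax.set_xlabel("recurrence gain r")
            ax.set_ylabel("normalized projection")
            ax.legend()
        elif stem == "recall_skew":
            for variant, sub in df.groupby("variant"):
                m = sub.groupby("state")["y_seed"].mean()
                ax.plot(m.index, m.values, label=variant)
            ax.axhline(0.5, color="gray", ls=":")
            ax.set_xlabel("state")
            ax.set_ylabel("seed output")
            ax.legend()
        else:
            sub = df[np.isclose(df.s, 0.0)]
            m = sub.groupby("state")["y_seed"].mean()
            ax.plot(m.index, m.values, "k-")
            ax.set_xlabel("state")
            ax.set_ylabel("seed output")
        _save(fig, name)
    return made
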