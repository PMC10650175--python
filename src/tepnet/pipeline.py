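"""Study orchestration: synthesize, estimate, connect, graph and contrast.

A single configuration (YAML or dict) fully determines a two-condition
synthetic study: montage, epoch geometry, ground-truth networks per
stimulation site, evoked-potential embedding, TEP estimation settings,
STOK/iPDC settings, graph thresholding and contrast alphas.  ``run_study``
materializes a deterministic directory tree

    outdir/
      manifest.json
      psychometrics/  pt.csv
      epochs/         <cond>_s<k>.h5
      teps/           <cond>_s<k>_<method>.csv, gmfp_<method>.csv
      connectivity/   <cond>_s<k>_edges.csv (window-aggregated networks)
      graphs/         betweenness.csv, degree.csv
      stats/          edges.csv, betweenness_edges.csv, degrees.csv,
                      gmfp_compare.csv, summary.json

Stages are isolated: a stage whose directory already carries its completion
marker is skipped, so deleting one stage directory and rerunning
regenerates only that stage and its dependents.  Every random draw derives
from the study seed and the (subject, condition) pair, so a rerun with the
same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._utils import time_axis
from .connectivity import (
    STOK,
    aggregate_windows,
    baseline_normalize,
    ipdc,
    spectral_transfer,
    windows_from_boundaries,
)
from .containers import EpochsArray, WindowedNetwork
from .graph import (
    edge_betweenness,
    flip_right_to_left,
    group_macro_areas,
    node_degree,
    threshold_at_fraction,
)
from .montage import macro_area_map, mirror_label, mirror_map, montage_preset
from .psychometrics import fit_logistic_mle, derive_pt, intensity_grid
from .stats import contrast_degrees, contrast_edges
from .synthetic import (
    embed_tep,
    ep_template,
    make_ground_truth_network,
    simulate_epochs,
    simulate_mocs_session,
)
from .tep import BayesianTEP, compare_gmfp, conventional_average, gmfp

__all__ = ["DEFAULT_CONFIG", "ConfigError", "validate_config", "run_study"]

logger = logging.getLogger(__name__)

#: Defaults mirror the experimental protocol: 18 subjects, the full
#: 59-channel montage, 500 Hz epochs of ±1000 ms and 6 blocks of 60 trials
#: per session.  Scaled-down studies override these explicitly.
DEFAULT_CONFIG = {
    "study": {"subjects": 18, "seed": 2023, "conditions": ["O1", "O2"]},
    "montage": "full59",
    "srate": 500.0,
    "times": {"start": -1000.0, "stop": 1000.0},
    "session": {"blocks": 6, "trials_per_block": 60},
    "network": {
        "order": 2,
        "diag": [0.5, -0.1],
        "noise_std": 1.0,
        "trial_noise_sd": 0.3,
        # common couplings, written in the left-stimulation (O1) frame and
        # mirrored for the O2 condition
        "couplings": [
            ["O1", "PO3", 1, 0.30, 12.0, 240.0],
            ["PO3", "P3", 1, 0.25, 24.0, 240.0],
            ["P3", "F3", 1, 0.20, 48.0, 240.0],
        ],
        # condition-specific extra couplings, taken literally per condition
        "effect_couplings": {"O1": [], "O2": []},
    },
    "ep": {"enabled": True, "amplitude": 1.0, "jitter_sd": 0.1},
    "mocs": {"alpha": 69.0, "beta": 0.8, "grid": [60.0, 78.0, 3.0],
             "n_per_level": 7},
    "tep": {"methods": ["ca", "bayes"], "prior_order": 2, "max_ar_order": 15,
            "reg": "auto"},
    "connectivity": {
        "order": 2,
        "band": [1.0, 40.0],
        "freq_step": 1.0,
        "window_boundaries": [12.0, 24.0, 48.0, 92.0, 124.0, 240.0],
        "baseline_window": [-240.0, -12.0],
    },
    "graph": {"threshold": 0.5},
    "stats": {"alpha_edges": 0.001, "alpha_gmfp": 0.05},
}


class ConfigError(ValueError):
    """Raised by validate_config with the full list of violations."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid study configuration:\n  " + "\n  ".join(errors))


def _deep_merge(base: dict, override: dict) -> dict:
    out = {}
    for k, v in base.items():
        if k in override and isinstance(v, dict) and isinstance(override[k], dict):
            out[k] = _deep_merge(v, override[k])
        elif k in override:
            out[k] = override[k]
        else:
            out[k] = v
    for k in override:
        if k not in base:
            out[k] = override[k]
    return out


def validate_config(config: dict | None = None) -> dict:
    """Merge a user config over the defaults and cross-check everything.

    Returns the fully-populated config; raises :class:`ConfigError` listing
    every violation with its path.
    """
    cfg = _deep_merge(DEFAULT_CONFIG, config or {})
    errors: list[str] = []

    montage = cfg["montage"]
    if isinstance(montage, str):
        try:
            montage = montage_preset(montage)
        except KeyError as e:
            errors.append(f"montage: {e}")
            montage = []
    cfg["montage"] = list(montage)
    labels = set(cfg["montage"])
    if len(labels) != len(cfg["montage"]):
        errors.append("montage: duplicate labels")
    if labels:
        try:
            mirror_map(cfg["montage"])
        except ValueError as e:
            errors.append(f"montage: {e}")

    if cfg["study"]["subjects"] < 1:
        errors.append("study.subjects: must be >= 1")
    for cond in cfg["study"]["conditions"]:
        if cond not in {"O1", "O2"}:
            errors.append(f"study.conditions: unknown condition {cond!r}")

    t = cfg["times"]
    if not t["start"] < 0 < t["stop"]:
        errors.append("times: need start < 0 < stop (pulse at t = 0)")
    if cfg["srate"] <= 0:
        errors.append("srate: must be positive")

    sess = cfg["session"]
    if sess["blocks"] < 1 or sess["trials_per_block"] < 1:
        errors.append("session: blocks and trials_per_block must be >= 1")

    net = cfg["network"]
    if net["order"] < 1:
        errors.append("network.order: must be >= 1")
    if len(net["diag"]) != net["order"]:
        errors.append("network.diag: needs one value per lag")
    all_couplings = list(net["couplings"])
    for cond, extra in net["effect_couplings"].items():
        all_couplings += list(extra)
    for c in all_couplings:
        if len(c) != 6:
            errors.append(f"network.couplings: malformed entry {c!r}")
            continue
        for lab in (c[0], c[1]):
            if labels and lab not in labels:
                errors.append(f"network.couplings: electrode {lab!r} not in montage")

    b = cfg["connectivity"]["window_boundaries"]
    if len(b) < 2 or any(x >= y for x, y in zip(b, b[1:])):
        errors.append("connectivity.window_boundaries: must be strictly increasing")
    elif b[-1] > t["stop"]:
        errors.append("connectivity.window_boundaries: exceed the epoch")
    lo, hi = cfg["connectivity"]["band"]
    if not 0 < lo < hi < cfg["srate"] / 2:
        errors.append("connectivity.band: must lie within (0, srate/2)")

    if not 0 <= cfg["graph"]["threshold"] <= 1:
        errors.append("graph.threshold: must lie in [0, 1]")
    for key in ("alpha_edges", "alpha_gmfp"):
        if not 0 < cfg["stats"][key] <= 1:
            errors.append(f"stats.{key}: must lie in (0, 1]")
    for m in cfg["tep"]["methods"]:
        if m not in {"ca", "bayes"}:
            errors.append(f"tep.methods: unknown method {m!r}")

    seeds = _subject_seeds(cfg)
    if len(set(seeds.values())) != len(seeds):
        errors.append("study.seed: derived per-(subject, condition) seeds collide")

    if errors:
        raise ConfigError(errors)
    return cfg


def _subject_seeds(cfg: dict) -> dict:
    """Deterministic unique seed per (subject, condition), < 2**31."""
    base = int(cfg["study"]["seed"])
    seeds = {}
    for ci, cond in enumerate(cfg["study"]["conditions"]):
        for s in range(int(cfg["study"]["subjects"])):
            ss = np.random.SeedSequence([base, ci, s])
            seeds[(cond, s)] = int(ss.generate_state(1)[0] & 0x7FFFFFFF)
    return seeds


def _condition_couplings(cfg: dict, cond: str) -> list:
    """Common couplings (mirrored for O2) plus the condition's extras."""
    common = [list(c) for c in cfg["network"]["couplings"]]
    if cond == "O2":
        common = [[mirror_label(c[0]), mirror_label(c[1]), *c[2:]] for c in common]
    extra = [list(c) for c in cfg["network"]["effect_couplings"].get(cond, [])]
    return common + extra


def _ep_topography(labels: list[str], stim_site: str) -> np.ndarray:
    """Deterministic nonuniform per-channel EP gain, largest at the site.

    Built in the left-stimulation frame and mirror-permuted for O2 so the
    two conditions are exchangeable after right-to-left flipping.
    """
    i0 = labels.index("O1")
    idx = np.arange(len(labels))
    topo = np.exp(-np.abs(idx - i0) / 5.0)
    if stim_site == "O2":
        mm = mirror_map(labels)
        pos = {lab: i for i, lab in enumerate(labels)}
        perm = np.array([pos[mm[lab]] for lab in labels])
        topo = topo[perm]
    return topo


def synthesize_subject_epochs(cfg: dict, cond: str, subject: int) -> EpochsArray:
    """Ground-truth network -> epochs -> embedded EP for one session."""
    times = time_axis(cfg["times"]["start"], cfg["times"]["stop"], cfg["srate"])
    labels = cfg["montage"]
    net = cfg["network"]
    d = len(labels)
    model = make_ground_truth_network(
        d, net["order"], _condition_couplings(cfg, cond),
        times=times, srate=cfg["srate"],
        noise_cov=net["noise_std"] ** 2 * np.eye(d),
        diag=tuple(net["diag"]), labels=labels,
    )
    seed = _subject_seeds(cfg)[(cond, subject)]
    n_trials = cfg["session"]["blocks"] * cfg["session"]["trials_per_block"]
    epochs = simulate_epochs(
        model, n_trials, times, seed, labels=labels, stim_site=cond,
        trial_noise_sd=net["trial_noise_sd"],
    )
    if cfg["ep"]["enabled"]:
        base = ep_template(times[times >= 0], amplitude=cfg["ep"]["amplitude"])
        topo = _ep_topography(labels, cond)
        epochs = embed_tep(epochs, topo[:, None] * base[None, :],
                           jitter_sd=cfg["ep"]["jitter_sd"], seed=seed + 1)
    return epochs


# ---------------------------------------------------------------------------
# stages

def _done(stage_dir: Path) -> bool:
    return (stage_dir / ".complete").exists()


def _mark_done(stage_dir: Path) -> None:
    (stage_dir / ".complete").write_text("ok\n")


def _stage_psychometrics(cfg, out: Path) -> None:
    stage = out / "psychometrics"
    if _done(stage):
        return
    stage.mkdir(parents=True, exist_ok=True)
    m = cfg["mocs"]
    grid = intensity_grid(*m["grid"])
    rows = []
    for s in range(cfg["study"]["subjects"]):
        seed = _subject_seeds(cfg)[(cfg["study"]["conditions"][0], s)] + 7919
        resp = simulate_mocs_session(m["alpha"], m["beta"], grid,
                                     m["n_per_level"], seed)
        fit = fit_logistic_mle(resp)
        rows.append({
            "subject": s, "alpha": fit.alpha, "beta": fit.beta,
            "converged": fit.converged,
            "pt": derive_pt(fit) if fit.converged else np.nan,
        })
    pd.DataFrame(rows).to_csv(stage / "pt.csv", index=False)
    _mark_done(stage)


def _stage_epochs(cfg, out: Path) -> None:
    stage = out / "epochs"
    if _done(stage):
        return
    stage.mkdir(parents=True, exist_ok=True)
    for cond in cfg["study"]["conditions"]:
        for s in range(cfg["study"]["subjects"]):
            t0 = time.perf_counter()
            epochs = synthesize_subject_epochs(cfg, cond, s)
            epochs.to_hdf5(stage / f"{cond}_s{s:02d}.h5")
            logger.info("epochs %s subject %d: %.2f s", cond, s,
                        time.perf_counter() - t0)
    _mark_done(stage)


def _stage_teps(cfg, out: Path) -> None:
    stage = out / "teps"
    if _done(stage):
        return
    stage.mkdir(parents=True, exist_ok=True)
    methods = cfg["tep"]["methods"]
    gmfp_rows = {m: [] for m in methods}
    for cond in cfg["study"]["conditions"]:
        for s in range(cfg["study"]["subjects"]):
            epochs = EpochsArray.from_hdf5(out / "epochs" / f"{cond}_s{s:02d}.h5")
            for method in methods:
                if method == "ca":
                    est = conventional_average(epochs)
                else:
                    est = BayesianTEP(
                        prior_order=cfg["tep"]["prior_order"],
                        max_ar_order=cfg["tep"]["max_ar_order"],
                        reg=cfg["tep"]["reg"],
                    ).fit(epochs).tep_
                df = pd.DataFrame(est.waveform.T, columns=epochs.labels)
                df.insert(0, "time_ms", est.times)
                df.to_csv(stage / f"{cond}_s{s:02d}_{method}.csv", index=False)
                g = gmfp(est)
                gmfp_rows[method].append({"cond": cond, "subject": s,
                                          **{f"t{k}": v for k, v in enumerate(g)}})
    for method in methods:
        pd.DataFrame(gmfp_rows[method]).to_csv(stage / f"gmfp_{method}.csv",
                                               index=False)
    _mark_done(stage)


def _subject_networks(cfg, epochs: EpochsArray):
    """STOK -> iPDC -> baseline-normalized windowed networks for one session."""
    conn = cfg["connectivity"]
    model = STOK(p=conn["order"]).fit(epochs).model_
    lo, hi = conn["band"]
    freqs = np.arange(lo, hi + 1e-9, conn["freq_step"])
    tensor = ipdc(spectral_transfer(model, freqs), model.innov_cov)
    windows = windows_from_boundaries(conn["window_boundaries"])
    post = aggregate_windows(tensor, windows, band=(lo, hi))
    pre = aggregate_windows(tensor, [tuple(conn["baseline_window"])],
                            band=(lo, hi))[0]
    return baseline_normalize(post, pre)


def _stage_connectivity(cfg, out: Path) -> None:
    stage = out / "connectivity"
    if _done(stage):
        return
    stage.mkdir(parents=True, exist_ok=True)
    for cond in cfg["study"]["conditions"]:
        for s in range(cfg["study"]["subjects"]):
            t0 = time.perf_counter()
            epochs = EpochsArray.from_hdf5(out / "epochs" / f"{cond}_s{s:02d}.h5")
            nets = _subject_networks(cfg, epochs)
            rows = []
            for net in nets:
                d = net.n_nodes
                for i in range(d):
                    for j in range(d):
                        if i != j:
                            rows.append({
                                "window_start": net.window[0],
                                "window_end": net.window[1],
                                "source": net.labels[j], "target": net.labels[i],
                                "weight": net.adjacency[i, j],
                            })
            pd.DataFrame(rows).to_csv(stage / f"{cond}_s{s:02d}_edges.csv",
                                      index=False)
            logger.info("connectivity %s subject %d: %.2f s", cond, s,
                        time.perf_counter() - t0)
    _mark_done(stage)


def _load_networks(cfg, out: Path, cond: str, s: int) -> list[WindowedNetwork]:
    df = pd.read_csv(out / "connectivity" / f"{cond}_s{s:02d}_edges.csv")
    labels = cfg["montage"]
    idx = {lab: i for i, lab in enumerate(labels)}
    nets = []
    for (a, b), grp in df.groupby(["window_start", "window_end"], sort=True):
        adj = np.zeros((len(labels), len(labels)))
        adj[grp["target"].map(idx), grp["source"].map(idx)] = grp["weight"]
        nets.append(WindowedNetwork(adjacency=adj, window=(a, b),
                                    band=tuple(cfg["connectivity"]["band"]),
                                    labels=labels))
    return nets


def _analysis_networks(cfg, out: Path):
    """Per-subject window networks with the O2 condition flipped to O1 frame."""
    result = {}
    for cond in cfg["study"]["conditions"]:
        per_subj = []
        for s in range(cfg["study"]["subjects"]):
            nets = _load_networks(cfg, out, cond, s)
            if cond == "O2":
                nets = [flip_right_to_left(n, cfg["montage"]) for n in nets]
            per_subj.append(nets)
        result[cond] = per_subj
    return result


def _stage_graphs(cfg, out: Path) -> None:
    stage = out / "graphs"
    if _done(stage):
        return
    stage.mkdir(parents=True, exist_ok=True)
    nets = _analysis_networks(cfg, out)
    frac = cfg["graph"]["threshold"]
    bet_rows, deg_rows = [], []
    for cond, per_subj in nets.items():
        for s, subj_nets in enumerate(per_subj):
            for net in subj_nets:
                # edge weights can be negative after baseline subtraction;
                # graph metrics operate on the positive part
                pos = net.copy(adjacency=np.clip(net.adjacency, 0.0, None))
                thr = threshold_at_fraction(pos, frac)
                bc = edge_betweenness(thr)
                deg = node_degree(thr)
                d = net.n_nodes
                for i in range(d):
                    deg_rows.append({
                        "cond": cond, "subject": s,
                        "window_start": net.window[0], "window_end": net.window[1],
                        "node": net.labels[i], "degree": int(deg[i]),
                    })
                    for j in range(d):
                        if bc[i, j] > 0:
                            bet_rows.append({
                                "cond": cond, "subject": s,
                                "window_start": net.window[0],
                                "window_end": net.window[1],
                                "source": net.labels[j], "target": net.labels[i],
                                "betweenness": bc[i, j],
                            })
    pd.DataFrame(bet_rows).to_csv(stage / "betweenness.csv", index=False)
    pd.DataFrame(deg_rows).to_csv(stage / "degree.csv", index=False)
    _mark_done(stage)


def _degree_pools(cfg, out: Path):
    deg = pd.read_csv(out / "graphs" / "degree.csv")
    areas = macro_area_map(cfg["montage"], stim_hemisphere="left")
    windows = windows_from_boundaries(cfg["connectivity"]["window_boundaries"])
    pools = {cond: {} for cond in cfg["study"]["conditions"]}
    area_labels = {}
    for lab, area in areas.items():
        area_labels.setdefault(area, []).append(lab)
    for cond in pools:
        sub = deg[deg["cond"] == cond]
        for win in windows:
            w = sub[(sub["window_start"] == win[0]) & (sub["window_end"] == win[1])]
            piv = w.pivot(index="subject", columns="node", values="degree")
            pools[cond][win] = {
                area: piv[labs].to_numpy(float)
                for area, labs in area_labels.items()
                if all(l in piv.columns for l in labs)
            }
    return pools


def _stage_stats(cfg, out: Path) -> None:
    stage = out / "stats"
    if _done(stage):
        return
    stage.mkdir(parents=True, exist_ok=True)
    conds = cfg["study"]["conditions"]
    summary = {}
    if len(conds) == 2:
        nets = _analysis_networks(cfg, out)
        a, b = conds
        edges = contrast_edges(nets[a], nets[b],
                               alpha=cfg["stats"]["alpha_edges"], labels=(a, b))
        edges.to_csv(stage / "edges.csv", index=False)
        summary["n_significant_edges"] = int(len(edges))

        # betweenness contrast on the per-subject thresholded graphs
        bet = pd.read_csv(out / "graphs" / "betweenness.csv")
        bet_nets = {}
        labels = cfg["montage"]
        idx = {lab: i for i, lab in enumerate(labels)}
        windows = windows_from_boundaries(cfg["connectivity"]["window_boundaries"])
        for cond in conds:
            per_subj = []
            for s in range(cfg["study"]["subjects"]):
                subj_nets = []
                sub = bet[(bet["cond"] == cond) & (bet["subject"] == s)]
                for win in windows:
                    w = sub[(sub["window_start"] == win[0])
                            & (sub["window_end"] == win[1])]
                    adj = np.zeros((len(labels), len(labels)))
                    if len(w):
                        adj[w["target"].map(idx), w["source"].map(idx)] = (
                            w["betweenness"]
                        )
                    subj_nets.append(WindowedNetwork(
                        adjacency=adj, window=win,
                        band=tuple(cfg["connectivity"]["band"]), labels=labels))
                per_subj.append(subj_nets)
            bet_nets[cond] = per_subj
        bet_edges = contrast_edges(bet_nets[a], bet_nets[b],
                                   alpha=cfg["stats"]["alpha_edges"],
                                   labels=(a, b))
        bet_edges.to_csv(stage / "betweenness_edges.csv", index=False)
        summary["n_significant_betweenness_edges"] = int(len(bet_edges))

        pools = _degree_pools(cfg, out)
        try:
            degrees = contrast_degrees(pools[a], pools[b],
                                       alpha=cfg["stats"]["alpha_edges"],
                                       labels=(a, b))
            degrees.to_csv(stage / "degrees.csv", index=False)
            summary["n_significant_degree_cells"] = int(degrees["significant"].sum())
        except ValueError as e:
            logger.warning("degree contrast skipped: %s", e)

    # GMFP: Bayesian estimator vs conventional averaging, per condition
    methods = cfg["tep"]["methods"]
    if {"ca", "bayes"} <= set(methods) and cfg["study"]["subjects"] >= 5:
        rows = []
        for cond in conds:
            per = {}
            for method in ("ca", "bayes"):
                df = pd.read_csv(out / "teps" / f"gmfp_{method}.csv")
                sub = df[df["cond"] == cond].sort_values("subject")
                per[method] = sub.filter(regex=r"^t\d+$").to_numpy(float)
            mask, p = compare_gmfp(per["bayes"], per["ca"],
                                   alpha=cfg["stats"]["alpha_gmfp"])
            rows.append({"cond": cond, "n_significant_samples": int(mask.sum()),
                         "n_samples": int(mask.size)})
        pd.DataFrame(rows).to_csv(stage / "gmfp_compare.csv", index=False)
        summary["gmfp_compare"] = rows
    (stage / "summary.json").write_text(json.dumps(summary, indent=2))
    _mark_done(stage)


def run_study(config: dict | None, outdir, subset: int | None = None) -> Path:
    """Validate the config and run every stage into ``outdir``.

    ``subset`` truncates the subject count (quick runs).  Returns the
    output directory; the manifest records the fully-expanded config, its
    hash and the derived per-(subject, condition) seeds.
    """
    cfg = validate_config(config)
    if subset is not None:
        cfg["study"]["subjects"] = min(cfg["study"]["subjects"], int(subset))
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(cfg, sort_keys=True, default=str)
    manifest = {
        "version": __version__,
        "config": cfg,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seeds": {f"{c}_s{s}": v for (c, s), v in _subject_seeds(cfg).items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    for stage_fn in (_stage_psychometrics, _stage_epochs, _stage_teps,
                     _stage_connectivity, _stage_graphs, _stage_stats):
        t0 = time.perf_counter()
        stage_fn(cfg, out)
        logger.info("%s: %.1f s", stage_fn.__name__, time.perf_counter() - t0)
    return out
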