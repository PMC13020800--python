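"""End-to-end pipeline: simulate -> fit -> spatial stats -> summaries -> links.

One JSON config drives the whole chain on synthetic data: a lattice patch
with per-ROI planted preference fields, forward-simulated beta weights, the
two-stage pRF fit, local Moran quadrant analysis, per-ROI global Moran and
variogram summaries, category/gradient summaries, an optional multi-subject
behavior-link stage (per-subject psychometric fits and the PSE-preference
correlation), and the long-range correlation matrix with its dendrogram.
Every stage writes headered TSV/JSON and is listed in a manifest with
content hashes; identical config + seed reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from chronotopo import behavior_link as bl
from chronotopo import longrange as lr
from chronotopo import spatial_stats as ss
from chronotopo import synthetic_data as sd
from chronotopo import topography_analysis as ta
from chronotopo import variogram as vg
from chronotopo.prf_model import FitConfig, StimulusSpec, TuningField, fit_field

log = logging.getLogger("chronotopo")

DEFAULT_CONFIG = {
    "seed": 0,
    "patch": {
        "n_rows": 12,
        "n_cols": 24,
        "spacing_mm": 2.0,
        "roi_blocks": [
            {
                "roi": "parietal_like",
                "stream": "IPS",
                "n_vertices": 144,
                "kind": "gradient",
                "params": {"axis": "x"},
            },
            {
                "roi": "frontal_like",
                "stream": "AI",
                "n_vertices": 144,
                "kind": "boundary",
                "params": {"center": 0.5, "spread": 0.03},
            },
        ],
    },
    "noise_sd": 0.05,
    "moran": {"n_perm": 999, "alpha": 0.05, "global_k": 12},
    "variogram": {"bin_width": 2.0},
    "ordering": {"parietal_like": 1, "frontal_like": 2},
    "behavior": {
        "n_subjects": 13,
        "n_per_duration": 40,
        "slope": 15.0,
        "pse_mean": 0.5,
        "pse_sd": 0.04,
        "subject_rows": 8,
        "subject_cols": 16,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path_or_dict) -> dict:
    """Merge a user config (path or dict) over the demo defaults."""
    if isinstance(path_or_dict, (str, Path)):
        user = json.loads(Path(path_or_dict).read_text())
    else:
        user = dict(path_or_dict or {})
    return _merge(DEFAULT_CONFIG, user)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _sub_seeds(master: int, n: int) -> list[int]:
    children = np.random.SeedSequence(master).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def build_patch_and_truth(cfg: dict, seed: int):
    """Lattice patch with per-ROI planted fields, concatenated."""
    pc = cfg["patch"]
    blocks = [
        sd.RoiBlock(b["roi"], b["n_vertices"], b.get("stream", "none"), b.get("hemisphere", "L"))
        for b in pc["roi_blocks"]
    ]
    patch = sd.make_patch(pc["n_rows"], pc["n_cols"], pc["spacing_mm"], blocks)
    seeds = _sub_seeds(seed, len(pc["roi_blocks"]))
    parts = []
    start = 0
    for b, s in zip(pc["roi_blocks"], seeds):
        n = b["n_vertices"]
        ids = np.arange(start, start + n)
        sub = sd.SurfacePatch(
            np.arange(n),
            patch.coords[ids],
            patch.roi[ids],
            patch.stream[ids],
            patch.hemisphere[ids],
        )
        parts.append(sd.plant_field(sub, b.get("kind", "white"), b.get("params"), seed=s))
        start += n
    truth = sd.GroundTruthField(
        np.concatenate([p.mu_true for p in parts]),
        np.concatenate([p.sigma_true for p in parts]),
        np.concatenate([p.gain_true for p in parts]),
        np.concatenate([p.baseline_true for p in parts]),
    )
    return patch, truth


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> dict:
    """Run every stage in dependency order; returns the output manifest."""
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stim = StimulusSpec()
    master = int(cfg["seed"])
    seed_field, seed_noise, seed_moran, seed_behavior = _sub_seeds(master, 4)
    outputs: dict[str, list[str]] = {}

    def emit(stage: str, name: str, obj) -> Path:
        path = outdir / name
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path, sep="\t", index=False)
        else:
            path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))
        outputs.setdefault(stage, []).append(name)
        return path

    # --- stage 1: simulate ------------------------------------------------
    patch, truth = build_patch_and_truth(cfg, seed_field)
    betas = sd.simulate_betas(truth, stim, cfg["noise_sd"], seed=seed_noise)
    emit("simulate", "patch.tsv", patch.to_frame())
    emit("simulate", "truth.tsv", truth.to_frame())
    emit("simulate", "betas.tsv", betas)

    # --- stage 2: pRF fit -------------------------------------------------
    field = fit_field(betas, patch, stim, FitConfig())
    emit("fit", "tuning_field.tsv", field.fits)
    emit("fit", "fit_summary.json", {"exclusions": field.exclusion_counts})

    # --- stage 3: local Moran + quadrants --------------------------------
    mcfg = cfg["moran"]
    valid = field.valid_mask
    roi_sizes = [int(np.count_nonzero(patch.roi[valid] == r)) for r in pd.unique(patch.roi)]
    k_local = ss.moran_neighborhood_size(roi_sizes)
    weights, ids = ss.knn_weights(patch, k_local, restrict="hemisphere", subset=valid)
    mu_valid = field.mu_d[valid]
    local = ss.local_morans_i(
        mu_valid, weights, n_perm=mcfg["n_perm"], alpha=mcfg["alpha"], seed=seed_moran
    )
    quad = ss.summarize_quadrants(local, patch.roi[valid])
    local_tbl = local.to_frame()
    local_tbl["vertex_id"] = ids
    emit("moran_local", "moran_local.tsv", local_tbl)
    emit("moran_local", "quadrant_summary.tsv", quad)
    emit(
        "moran_local",
        "moran_local_meta.json",
        {"k": k_local, "n_perm": mcfg["n_perm"], "alpha": mcfg["alpha"], "seed": seed_moran,
         "centering": "hemisphere_mean", "alternative": "two-sided"},
    )

    # --- stage 4: global Moran + variogram per ROI -----------------------
    rows = []
    for roi in pd.unique(patch.roi):
        sel = (patch.roi == roi) & valid
        vals = field.mu_d[sel]
        row = {"roi": roi, "n_valid": int(sel.sum())}
        if sel.sum() > max(mcfg["global_k"] + 1, 3) and np.ptp(vals) > 0:
            w_roi, _ = ss.knn_weights(patch, mcfg["global_k"], restrict="roi", subset=sel)
            gi, gp = ss.global_morans_i(vals, w_roi, n_perm=mcfg["n_perm"], seed=seed_moran)
            sub_d = patch.distance_matrix()[np.ix_(sel, sel)]
            v = vg.empirical_variogram(vals, distances=sub_d, bin_width=cfg["variogram"]["bin_width"])
            rng_frac, reached = vg.extract_range(v)
            row.update(
                global_i=gi, global_p=gp, nugget=vg.extract_nugget(v),
                range_fraction=rng_frac, reached_sill=reached,
            )
        else:
            log.warning("ROI %s too small for global Moran/variogram; skipped", roi)
            row.update(global_i=np.nan, global_p=np.nan, nugget=np.nan,
                       range_fraction=np.nan, reached_sill=False)
        rows.append(row)
    emit("topography", "topography_roi.tsv", pd.DataFrame(rows))

    # --- stage 5: categories + hierarchy gradients -----------------------
    ordering = {k: float(v) for k, v in cfg["ordering"].items()}
    summary = ta.summarize_roi(field, quadrants=quad, ordering=ordering)
    emit("summaries", "roi_summary.tsv", summary)
    grads = {}
    for col in ("median_mu", "ll_minus_hh"):
        sub = summary.dropna(subset=[col, "hierarchy_rank"])
        if len(sub) >= 3:
            g = ta.hierarchy_regression(sub[col], sub["hierarchy_rank"])
            grads[col] = {"slope": g.slope, "intercept": g.intercept,
                          "t_stat": g.t_stat, "p_value": g.p_value, "n": g.n}
    emit("summaries", "gradients.json", grads)

    # --- stage 6: preference map -----------------------------------------
    m, xc, yc = ta.render_preference_map(field)
    emit("maps", "preference_map.tsv",
         pd.DataFrame(m, index=pd.Index(yc, name="y_mm"), columns=xc).reset_index())

    # --- stage 7: behavior link + long-range (optional) ------------------
    bcfg = cfg.get("behavior")
    if not bcfg:
        log.info("no behavior config: behavior-link stage skipped")
        outputs["behavior_link"] = []
    else:
        _run_group_stage(cfg, bcfg, stim, ordering, seed_behavior, emit)

    manifest = {
        "config": cfg,
        "sub_seeds": {"field": seed_field, "noise": seed_noise,
                      "moran": seed_moran, "behavior": seed_behavior},
        "stages": outputs,
        "hashes": {n: _sha256(outdir / n) for ns in outputs.values() for n in ns},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _run_group_stage(cfg, bcfg, stim, ordering, seed: int, emit) -> None:
    """Multi-subject twin: per-subject planted fields (the boundary ROI is
    centered on each subject's planted PSE), pRF fits, psychometric fits,
    the PSE-preference link, and the long-range correlation structure."""
    n_subj = int(bcfg["n_subjects"])
    rng = np.random.default_rng(seed)
    pses = bcfg["pse_mean"] + bcfg["pse_sd"] * rng.standard_normal(n_subj)
    seeds = _sub_seeds(seed + 1, 2 * n_subj)

    sub_cfg = {
        "patch": {
            "n_rows": bcfg["subject_rows"],
            "n_cols": bcfg["subject_cols"],
            "spacing_mm": cfg["patch"]["spacing_mm"],
            "roi_blocks": [
                dict(b, n_vertices=bcfg["subject_rows"] * bcfg["subject_cols"]
                     // len(cfg["patch"]["roi_blocks"]))
                for b in cfg["patch"]["roi_blocks"]
            ],
        }
    }
    psych_rows, medians = [], {}
    for s in range(n_subj):
        scfg = json.loads(json.dumps(sub_cfg))
        for b in scfg["patch"]["roi_blocks"]:
            if b.get("kind") == "boundary":
                b.setdefault("params", {})["center"] = float(pses[s])
        patch_s, truth_s = build_patch_and_truth(scfg, seeds[2 * s])
        betas_s = sd.simulate_betas(truth_s, stim, cfg["noise_sd"], seed=seeds[2 * s] + 1)
        field_s = fit_field(betas_s, patch_s, stim, FitConfig())
        med = {}
        for roi in pd.unique(patch_s.roi):
            sel = (patch_s.roi == roi) & field_s.valid_mask
            med[roi] = float(np.median(field_s.mu_d[sel])) if sel.any() else np.nan
        sid = f"s{s:02d}"
        medians[sid] = med
        beh = sd.simulate_behavior(
            float(pses[s]), bcfg["slope"], int(bcfg["n_per_duration"]),
            seed=seeds[2 * s + 1], subject_id=sid,
        )
        fit = bl.fit_psychometric(beh)
        psych_rows.append(
            {"subject": sid, "pse_true": float(pses[s]), "pse": fit.pse,
             "slope": fit.slope, "intercept": fit.intercept, "converged": fit.converged}
        )

    psych = pd.DataFrame(psych_rows)
    med_df = pd.DataFrame(medians).T  # subject x region
    med_df.index.name = "subject"
    emit("behavior_link", "psychometrics.tsv", psych)
    emit("behavior_link", "subject_medians.tsv", med_df.reset_index())

    link = bl.pse_preference_link(
        psych.set_index("subject")["pse"], med_df, ordering, clamp=True
    )
    emit("behavior_link", "pse_link.tsv", link.table)
    if link.gradient is not None:
        emit("behavior_link", "pse_link_gradient.json",
             {"slope": link.gradient.slope, "t_stat": link.gradient.t_stat,
              "p_value": link.gradient.p_value, "n": link.gradient.n})

    corr = lr.preference_corr_matrix(med_df)
    emit("longrange", "corr_matrix.tsv", corr.tau.reset_index(names="region"))
    if not corr.tau.isna().any().any():
        dend = lr.hierarchical_cluster(lr.corr_to_distance(corr))
        emit("longrange", "dendrogram.json",
             {"newick": dend.to_newick(), "leaf_order": dend.leaf_order(),
              "merge_heights": [float(h) for h in dend.heights]})
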