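"""End-to-end screen orchestration.

``run_screen`` drives the whole analysis from a single config: gather
per-arena worm positions (from TIFF scans plus a metadata table, or from the
synthetic generator), summarize each arena, apply QC, pool worms per
condition, compute bootstrap effect sizes against the null references, apply
FDR correction, and emit valence (and, when all four genotypes are present,
channel-dependence) calls.  All of the screen's constants — area bounds, the
150-worm QC floor, 5,000 resamples, 5% FDR, the 32.5 mm nominal half-width —
live in the config so a run is a single auditable document.

Outputs: location CSVs (one per arena), ``summary.csv``, ``effects.csv``,
``dd.csv`` + ``calls.csv`` (when computable), and a plain-text log with
per-stage counts.  Re-running with the same config and seed is byte-identical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import classify as cls
from . import imaging, io, metrics, stats, synthetic

__all__ = ["ScreenResult", "default_config", "run_screen"]


DEFAULTS = {
    "seed": 0,
    "qc_min_worms": metrics.QC_MIN_WORMS,
    "n_resamples": stats.DEFAULT_RESAMPLES,
    "fdr": 0.05,
    "half_width_mm": metrics.NOMINAL_HALF_WIDTH_MM,
    "min_area": imaging.MIN_WORM_AREA,
    "max_area": imaging.MAX_WORM_AREA,
    "wells_per_plate": 4,
    "controls": {"primary": "DMSO:DMSO", "secondary": "DMSO:water"},
    "strains": {},  # optional roles: wild_type/tax4/osm9/double -> strain_id
}


@dataclass
class ScreenResult:
    summaries: pd.DataFrame
    effects: pd.DataFrame
    calls: pd.DataFrame
    dd: pd.DataFrame
    positions: dict[tuple[str, str], np.ndarray]
    log: list[str] = field(default_factory=list)


def default_config(**overrides) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULTS.items()}
    cfg.update(overrides)
    return cfg


def _load_config(config) -> dict:
    if isinstance(config, (str, os.PathLike)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = default_config()
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k] = {**cfg[k], **v}
        else:
            cfg[k] = v
    return cfg


def _axis_position_px(table: imaging.LocationTable) -> np.ndarray:
    """Gradient-axis pixel position measured from the test apex."""
    det = table.detection
    x = table.rows["x_px"].to_numpy(dtype=float)
    if det.test_side == "left":
        pos = x - det.apex_test[0]
    else:
        pos = det.apex_test[0] - x
    return np.clip(pos, 0.0, det.w)


def _gather_from_scans(cfg: dict, log: list[str]):
    """(arena rows, z-positions) from TIFF scans joined to metadata."""
    meta = io.load_metadata(cfg["metadata"])
    arenas = []
    for path in cfg["scans"]:
        scan = imaging.read_scan(path, dpi=int(cfg.get("dpi", 1200)))
        tables = imaging.locate_worms(
            scan,
            min_area=cfg["min_area"],
            max_area=cfg["max_area"],
            wells_per_plate=cfg["wells_per_plate"],
        )
        log.append(f"{scan.image_id}: {len(tables)} arenas located")
        for t in tables:
            det = t.detection
            key = (scan.image_id, str(det.slot), det.well_id)
            row = meta[
                (meta.image_id == key[0])
                & (meta.slot == key[1])
                & (meta.well_id == key[2])
            ]
            if row.empty:
                raise io.MetadataError(f"no metadata for arena {key}")
            rec = row.iloc[0]
            geom = metrics.ArenaGeometry(w=det.w, dpi=scan.dpi, test_side=det.test_side)
            pos = metrics.to_gradient_coords(_axis_position_px(t), geom)
            arenas.append(
                {
                    "table": t,
                    "z": pos.z,
                    "compound_id": rec.compound_id,
                    "strain_id": rec.strain_id,
                    "image_id": key[0],
                    "plate_id": str(getattr(rec, "plate_id", "")),
                    "arena_id": t.arena_id,
                    "w_px": det.w,
                }
            )
    return arenas


def _gather_synthetic(cfg: dict, log: list[str]):
    """Per-arena positions from the synthetic generator.

    Each condition entry gives compound, strain and a drift model; arenas are
    independent draws.  With ``render_images: true`` every arena is rendered
    to an image and passed through the full imaging path, otherwise the
    sampled positions are used directly.
    """
    syn = cfg["synthetic"]
    n_arenas = int(syn.get("arenas_per_condition", 3))
    n_worms = int(syn.get("worms_per_arena", 250))
    sigma = float(syn.get("sigma_mm", 10.0))
    half_width = float(cfg["half_width_mm"])
    render = bool(syn.get("render_images", False))
    dpi = int(syn.get("dpi", 1200))
    base_seed = int(cfg["seed"])

    arenas = []
    for ci, cond in enumerate(syn["conditions"]):
        compound = cond["compound"]
        strain = cond.get("strain", "N2")
        mu = float(cond.get("drift_mu", 0.0))
        cond_sigma = float(cond.get("sigma_mm", sigma))
        for ai in range(n_arenas):
            seed = (base_seed * 9973 + ci * 131 + ai) % (2**31)
            model = synthetic.PositionModel(
                drift_mu=mu,
                spread_sigma=cond_sigma,
                half_width_L=half_width - 1.6 if render else half_width,
                n_worms=n_worms,
                seed=seed,
            )
            table = synthetic.sample_endpoint_positions(model)
            arena_id = f"SYN{ci:02d}_{ai + 1}_A"
            if render:
                scale = dpi / synthetic.REFERENCE_DPI
                spec = synthetic.SyntheticArenaSpec(
                    dpi=dpi,
                    image_width_px=int(3300 * scale),
                    image_height_px=int(1100 * scale),
                    worm_count=n_worms,
                    seed=seed,
                    arena_id=arena_id,
                )
                img, _gt = synthetic.render_positions_arena(spec, table.z, seed=seed)
                scan = imaging.GrayscaleScan(img, dpi=dpi, image_id=f"SYN{ci:02d}{ai:02d}")
                s2 = scale**2
                located = imaging.locate_worms(
                    scan,
                    min_area=max(1, int(cfg["min_area"] * s2)),
                    max_area=max(2, int(cfg["max_area"] * s2)),
                    wells_per_plate=1,
                )[0]
                det = located.detection
                geom = metrics.ArenaGeometry(w=det.w, dpi=dpi, test_side=det.test_side)
                z = metrics.to_gradient_coords(_axis_position_px(located), geom).z
                w_px = det.w
                loc_table = located
            else:
                z = table.z
                w_px = synthetic.REFERENCE_W_PX * dpi / synthetic.REFERENCE_DPI
                loc_table = None
            arenas.append(
                {
                    "table": loc_table,
                    "z": z,
                    "compound_id": compound,
                    "strain_id": strain,
                    "image_id": f"SYN{ci:02d}{ai:02d}",
                    "plate_id": f"p{ci:02d}{ai:02d}",
                    "arena_id": arena_id,
                    "w_px": w_px,
                }
            )
    log.append(f"synthetic mode: {len(arenas)} arenas generated")
    return arenas


def run_screen(config, out_dir: str | os.PathLike | None = None) -> ScreenResult:
    """Run the full screen described by ``config`` (dict or YAML path)."""
    cfg = _load_config(config)
    log: list[str] = []

    if "synthetic" in cfg:
        arenas = _gather_synthetic(cfg, log)
    elif "scans" in cfg:
        arenas = _gather_from_scans(cfg, log)
    else:
        raise ValueError("config must provide either 'scans' or a 'synthetic' section")

    # per-arena summaries + QC
    qc_min = int(cfg["qc_min_worms"])
    w_mm = 2 * float(cfg["half_width_mm"])
    summary_rows = []
    pooled: dict[tuple[str, str], list[np.ndarray]] = {}
    n_excluded = 0
    for a in arenas:
        pos = metrics.PositionTable(z=a["z"], arena_id=a["arena_id"])
        geom = metrics.ArenaGeometry(w=a["w_px"])
        s = metrics.summarize_arena(
            pos,
            geom,
            compound_id=a["compound_id"],
            strain_id=a["strain_id"],
            image_id=a["image_id"],
            plate_id=a["plate_id"],
            arena_id=a["arena_id"],
            qc_threshold=qc_min,
            w_mm=w_mm,
        )
        summary_rows.append(s.__dict__)
        if s.qc_pass:
            pooled.setdefault((a["compound_id"], a["strain_id"]), []).append(pos.z)
        else:
            n_excluded += 1
            log.append(
                f"QC exclude {a['arena_id']}: {s.n_total} worms < {qc_min}"
            )
    summaries = pd.DataFrame(summary_rows)
    log.append(
        f"{len(arenas)} arenas summarized, {n_excluded} excluded by QC "
        f"(<{qc_min} worms)"
    )

    positions = {k: np.concatenate(v) for k, v in pooled.items()}
    if not positions:
        import warnings

        warnings.warn("every arena failed QC; effects table will be empty")

    # effect sizes vs the two null references, per strain
    primary = cfg["controls"]["primary"]
    secondary = cfg["controls"].get("secondary")
    n_resamples = int(cfg["n_resamples"])
    seed = int(cfg["seed"])
    effect_rows = []
    effects_by_key: dict[tuple[str, str, str], stats.EffectSize] = {}
    strains = sorted({k[1] for k in positions})
    for strain in strains:
        ctrl = positions.get((primary, strain))
        ctrl2 = positions.get((secondary, strain)) if secondary else None
        compounds = sorted(
            c for (c, s) in positions if s == strain and c not in (primary, secondary)
        )
        if ctrl is None or len(ctrl) < 2:
            if compounds:
                log.append(f"warning: no pooled {primary} control for strain {strain}")
            continue
        for compound in compounds:
            test = positions[(compound, strain)]
            for null_name, null_sample in (
                (primary, ctrl),
                (secondary, ctrl2),
            ):
                if null_name is None or null_sample is None or len(null_sample) < 2:
                    continue
                label = f"{strain}|{compound}|vs|{null_name}"
                eff = stats.bootstrap_mean_difference(
                    test, null_sample, n_resamples=n_resamples, seed=seed, label=label
                )
                effects_by_key[(strain, compound, null_name)] = eff
                effect_rows.append(
                    {
                        "strain_id": strain,
                        "compound_id": compound,
                        "reference": null_name,
                        "n_test": eff.n_test,
                        "n_control": eff.n_control,
                        "mean_difference": eff.mean_difference,
                        "ci_low": eff.ci_low,
                        "ci_high": eff.ci_high,
                        "p_value": eff.p_value,
                    }
                )
    effects = pd.DataFrame(effect_rows)

    # BH correction within each (strain, reference) family
    if not effects.empty:
        effects["adjusted_p"] = np.nan
        effects["rejected"] = False
        for (_s, _r), grp in effects.groupby(["strain_id", "reference"]):
            recs = stats.benjamini_hochberg(grp["p_value"].tolist(), fdr=float(cfg["fdr"]))
            effects.loc[grp.index, "adjusted_p"] = [r.adjusted_p for r in recs]
            effects.loc[grp.index, "rejected"] = [r.rejected for r in recs]

    # valence calls for the wild-type strain (or the only strain present)
    roles = cfg.get("strains") or {}
    wt = roles.get("wild_type") or (strains[0] if len(strains) == 1 else None)
    call_rows = []
    if wt is not None and not effects.empty:
        wt_eff = effects[effects.strain_id == wt]
        for compound in sorted(wt_eff.compound_id.unique()):
            e1 = effects_by_key.get((wt, compound, primary))
            e2 = effects_by_key.get((wt, compound, secondary))
            if e1 is None or e2 is None:
                continue
            row = wt_eff[(wt_eff.compound_id == compound) & (wt_eff.reference == primary)]
            padj = stats.PAdjustRecord(
                raw_p=float(row.p_value.iloc[0]),
                adjusted_p=float(row.adjusted_p.iloc[0]),
                rejected=bool(row.rejected.iloc[0]),
            )
            call = cls.classify_valence(e1, e2, padj, compound_id=compound)
            call_rows.append(
                {
                    "compound_id": compound,
                    "chemoactive": call.chemoactive,
                    "valence": call.valence,
                    "putative_false_positive": call.putative_false_positive,
                    "ambiguous": call.ambiguous,
                }
            )
    calls = pd.DataFrame(call_rows)

    # delta-delta panels + dependence classes when all four genotypes exist
    dd_rows = []
    have_roles = all(r in roles for r in ("wild_type", "tax4", "osm9", "double"))
    if have_roles and not effects.empty:
        pair_defs = {
            "tax4_vs_wt": (roles["tax4"], roles["wild_type"]),
            "osm9_vs_wt": (roles["osm9"], roles["wild_type"]),
            "double_vs_wt": (roles["double"], roles["wild_type"]),
            "tax4_vs_double": (roles["tax4"], roles["double"]),
            "osm9_vs_double": (roles["osm9"], roles["double"]),
        }
        compounds = sorted(
            {c for (c, s) in positions if c not in (primary, secondary)}
        )
        dd_by_compound: dict[str, dict[str, stats.DeltaDelta]] = {}
        for compound in compounds:
            panel = {}
            for name, (s1, s2) in pair_defs.items():
                needed = [
                    (primary, s1), (compound, s1), (primary, s2), (compound, s2),
                ]
                if any(k not in positions for k in needed):
                    panel = None
                    break
                panel[name] = stats.delta_delta(
                    positions[(primary, s1)],
                    positions[(compound, s1)],
                    positions[(primary, s2)],
                    positions[(compound, s2)],
                    n_resamples=n_resamples,
                    seed=seed,
                    label=f"dd|{compound}|{name}",
                )
            if panel is None:
                continue
            dd_by_compound[compound] = panel
            for name, d in panel.items():
                dd_rows.append(
                    {
                        "compound_id": compound,
                        "comparison": name,
                        "delta1": d.delta1,
                        "delta2": d.delta2,
                        "delta_delta": d.delta_delta,
                        "abs_dd": d.abs_value,
                        "ci_low": d.ci_low,
                        "ci_high": d.ci_high,
                    }
                )
        if dd_by_compound:
            rubric = cls.quartile_rubric(
                [d.abs_value for p in dd_by_compound.values() for d in p.values()]
            )
            log.append(
                f"|DD| rubric: median {rubric.median_threshold:.2f} mm, "
                f"edges {rubric.quartile_edges}"
            )
            dep_by_compound = {}
            for compound, panel in dd_by_compound.items():
                mut_effs = {
                    r: effects_by_key.get((roles[r], compound, primary))
                    for r in ("tax4", "osm9")
                }
                mut_effs = {k: v for k, v in mut_effs.items() if v is not None}
                dep = cls.classify_dependence(
                    panel,
                    rubric,
                    compound_id=compound,
                    wt_effect=effects_by_key.get((wt, compound, primary)),
                    mutant_effects=mut_effs,
                )
                dep_by_compound[compound] = dep
            if not calls.empty:
                calls["dependence_class"] = [
                    dep_by_compound[c].dependence_class
                    if c in dep_by_compound else ""
                    for c in calls.compound_id
                ]
                calls["inversion"] = [
                    dep_by_compound[c].inversion if c in dep_by_compound else False
                    for c in calls.compound_id
                ]
    dd = pd.DataFrame(dd_rows)

    result = ScreenResult(
        summaries=summaries, effects=effects, calls=calls, dd=dd,
        positions=positions, log=log,
    )
    if out_dir is not None:
        _write_outputs(result, arenas, out_dir)
    return result


def _write_outputs(result: ScreenResult, arenas, out_dir) -> None:
    os.makedirs(out_dir, exist_ok=True)
    loc_dir = os.path.join(out_dir, "locations")
    os.makedirs(loc_dir, exist_ok=True)
    for a in arenas:
        t = a["table"]
        if t is not None and t.detection is not None:
            name = io.encode_location_name(
                a["image_id"], t.detection.slot, t.detection.well_id
            )
            t.to_csv(os.path.join(loc_dir, name))
    result.summaries.to_csv(os.path.join(out_dir, "summary.csv"), index=False)
    result.effects.to_csv(os.path.join(out_dir, "effects.csv"), index=False)
    if not result.calls.empty:
        result.calls.to_csv(os.path.join(out_dir, "calls.csv"), index=False)
    if not result.dd.empty:
        result.dd.to_csv(os.path.join(out_dir, "dd.csv"), index=False)
    with open(os.path.join(out_dir, "run.log"), "w") as fh:
        fh.write("\n".join(result.log) + "\n")
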