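"""Recompute screen-level numbers from deposited per-worm position tables.

The published screen deposited its raw per-worm gradient positions as
supplementary spreadsheets.  When those files are placed under
``data/supplementary/`` (they are not redistributed with this package), the
functions here recompute the headline quantities directly from the raw
positions: pooled mean differences of the reference compounds against the
symmetric-solvent null, screen-wide valence counts, and the quartiles of the
pooled |DD| distribution.

Expected layout (either the original ``.xlsx`` files or sheets exported to
``.csv``): long-format tables with one row per worm and columns naming the
condition/compound, the strain, and the gradient position ``z`` in mm.
Column names are matched case-insensitively against common variants.
"""

from __future__ import annotations

import glob
import os

import numpy as np
import pandas as pd

from . import classify as cls
from . import stats

__all__ = [
    "SupplementaryDataMissing",
    "load_position_tables",
    "pooled_reference_effects",
    "screen_valence_counts",
    "dd_distribution_stats",
]

_CONDITION_ALIASES = ("condition", "compound", "compound_id", "sm", "test_compound")
_STRAIN_ALIASES = ("strain", "strain_id", "genotype")
_POSITION_ALIASES = ("z", "z_mm", "position", "position_mm", "mean_position", "x_mm")

REFERENCE_CONDITIONS = (
    "isoamyl alcohol",
    "diacetyl",
    "2-nonanone",
    "1-octanol",
    "DMSO:water",
    "Empty:Empty",
)


class SupplementaryDataMissing(FileNotFoundError):
    pass


def _find_column(df: pd.DataFrame, aliases) -> str | None:
    lower = {c.lower().strip(): c for c in df.columns}
    for a in aliases:
        if a in lower:
            return lower[a]
    return None


def load_position_tables(data_dir) -> pd.DataFrame:
    """Load per-worm position tables from ``data_dir``.

    Accepts any mix of ``.csv``/``.xlsx`` files; returns a normalized frame
    with columns ``condition``, ``strain``, ``z_mm``.  Raises
    :class:`SupplementaryDataMissing` when no usable file is present.
    """
    paths = sorted(
        glob.glob(os.path.join(str(data_dir), "*.csv"))
        + glob.glob(os.path.join(str(data_dir), "*.xlsx"))
    )
    frames = []
    for path in paths:
        if path.endswith(".xlsx"):
            sheets = pd.read_excel(path, sheet_name=None)
            dfs = list(sheets.values())
        else:
            dfs = [pd.read_csv(path)]
        for df in dfs:
            cond = _find_column(df, _CONDITION_ALIASES)
            zcol = _find_column(df, _POSITION_ALIASES)
            if cond is None or zcol is None:
                continue
            strain = _find_column(df, _STRAIN_ALIASES)
            out = pd.DataFrame(
                {
                    "condition": df[cond].astype(str),
                    "strain": df[strain].astype(str) if strain else "N2",
                    "z_mm": pd.to_numeric(df[zcol], errors="coerce"),
                }
            ).dropna(subset=["z_mm"])
            if len(out):
                frames.append(out)
    if not frames:
        raise SupplementaryDataMissing(
            f"no per-worm position tables found under {data_dir!r}; place the "
            "deposited supplementary spreadsheets (or CSV exports with "
            "condition/strain/z columns) there to run the reproduction"
        )
    return pd.concat(frames, ignore_index=True)


def pooled_reference_effects(
    positions: pd.DataFrame,
    null_condition: str = "DMSO:DMSO",
    strain: str = "N2",
    conditions=REFERENCE_CONDITIONS,
    n_resamples: int = stats.DEFAULT_RESAMPLES,
    seed: int = 0,
) -> pd.DataFrame:
    """Pooled mean differences of reference conditions vs the symmetric null.

    Point estimates are deterministic (plain differences of means over the
    pooled worms); CIs are bootstrapped.
    """
    df = positions[positions.strain == strain]
    ctrl = df.loc[df.condition == null_condition, "z_mm"].to_numpy()
    rows = []
    for cond in conditions:
        sample = df.loc[df.condition == cond, "z_mm"].to_numpy()
        if sample.size < 2 or ctrl.size < 2:
            continue
        eff = stats.bootstrap_mean_difference(
            sample, ctrl, n_resamples=n_resamples, seed=seed, label=f"ref|{cond}"
        )
        rows.append(
            {
                "condition": cond,
                "mean_difference": eff.mean_difference,
                "ci_low": eff.ci_low,
                "ci_high": eff.ci_high,
                "n": eff.n_test,
            }
        )
    return pd.DataFrame(rows)


def screen_valence_counts(
    positions: pd.DataFrame,
    strain: str = "N2",
    nulls: tuple[str, str] = ("DMSO:DMSO", "DMSO:water"),
    references=("isoamyl alcohol", "diacetyl", "2-nonanone", "1-octanol"),
    n_resamples: int = stats.DEFAULT_RESAMPLES,
    seed: int = 0,
    fdr: float = 0.05,
) -> dict:
    """Chemoactive / attractant / repellent counts over the screened library."""
    df = positions[positions.strain == strain]
    ctrl1 = df.loc[df.condition == nulls[0], "z_mm"].to_numpy()
    ctrl2 = df.loc[df.condition == nulls[1], "z_mm"].to_numpy()
    compounds = sorted(
        c for c in df.condition.unique() if c not in nulls and c not in references
    )
    calls = []
    pvals = []
    effs = []
    for c in compounds:
        sample = df.loc[df.condition == c, "z_mm"].to_numpy()
        e1 = stats.bootstrap_mean_difference(
            sample, ctrl1, n_resamples=n_resamples, seed=seed, label=f"scr|{c}|1"
        )
        e2 = stats.bootstrap_mean_difference(
            sample, ctrl2, n_resamples=n_resamples, seed=seed, label=f"scr|{c}|2"
        )
        pvals.append(e1.p_value)
        effs.append((c, e1, e2))
    records = stats.benjamini_hochberg(pvals, fdr=fdr)
    for (c, e1, e2), rec in zip(effs, records):
        calls.append(cls.classify_valence(e1, e2, rec, compound_id=c))
    active = [c for c in calls if c.chemoactive]
    return {
        "n_compounds": len(compounds),
        "n_chemoactive": len(active),
        "n_attractants": sum(c.valence == "attractant" for c in active),
        "n_repellents": sum(c.valence == "repellent" for c in active),
        "putative_false_positives": sorted(
            c.compound_id for c in active if c.putative_false_positive
        ),
    }


def dd_distribution_stats(
    positions: pd.DataFrame,
    roles: dict[str, str],
    null_condition: str = "DMSO:DMSO",
    n_resamples: int = stats.DEFAULT_RESAMPLES,
    seed: int = 0,
) -> dict:
    """Min/median/max and quartile edges of the pooled |DD| distribution.

    ``roles`` maps wild_type/tax4/osm9/double to strain names as used in the
    position tables; the pooled set covers every compound x genotype-pair
    comparison, mirroring the published rubric table.
    """
    pair_defs = {
        "tax4_vs_wt": (roles["tax4"], roles["wild_type"]),
        "osm9_vs_wt": (roles["osm9"], roles["wild_type"]),
        "double_vs_wt": (roles["double"], roles["wild_type"]),
        "tax4_vs_double": (roles["tax4"], roles["double"]),
        "osm9_vs_double": (roles["osm9"], roles["double"]),
    }
    compounds = sorted(
        c for c in positions.condition.unique() if c != null_condition
    )
    values = []
    for compound in compounds:
        for name, (s1, s2) in pair_defs.items():
            def grab(cond, s):
                return positions.loc[
                    (positions.condition == cond) & (positions.strain == s), "z_mm"
                ].to_numpy()

            g1c, g1t = grab(null_condition, s1), grab(compound, s1)
            g2c, g2t = grab(null_condition, s2), grab(compound, s2)
            if min(g.size for g in (g1c, g1t, g2c, g2t)) < 2:
                continue
            d = stats.delta_delta(
                g1c, g1t, g2c, g2t, n_resamples=n_resamples, seed=seed,
                label=f"dd|{compound}|{name}",
            )
            values.append(d.abs_value)
    if len(values) < 4:
        raise ValueError("too few |DD| values to form quartiles")
    arr = np.asarray(values)
    rubric = cls.quartile_rubric(arr)
    return {
        "n_comparisons": int(arr.size),
        "min": float(arr.min()),
        "median": rubric.median_threshold,
        "max": float(arr.max()),
        "quartile_edges": rubric.quartile_edges,
    }
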