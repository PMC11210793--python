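"""Categorical calls from effect sizes: valence and channel dependence.

A compound is **chemoactive** when its mean-difference CI excludes zero
against at least one of the two null reference conditions (symmetric
DMSO:DMSO and asymmetric DMSO:water); its **valence** (attractant/repellent)
is the sign of the DMSO:DMSO mean difference.  Compounds whose significance
does not survive FDR correction are flagged putative false positives rather
than dropped.

Chemosensory transduction in C. elegans funnels through two effector ion
channels, the cyclic-nucleotide-gated TAX-4 and the TRPV channel OSM-9; the
double mutant is anosmic.  Which channel a response relies on is read off a
panel of two-factor |DD| contrasts between genotype pairs, binned by the
quartiles of the pooled |DD| distribution: values above the pooled median
count as a substantial difference between the two genotypes, values below as
modest.  The rubric for a response carried primarily by one channel is:

* substantial (>median) difference between that channel's single mutant and
  wild type;
* modest (<median) difference between that single mutant and the anosmic
  double mutant; and
* modest (<median) difference between the *other* single mutant and wild type.

Responses requiring both channels (either knockout phenocopies the double
mutant) or served redundantly by either (both knockouts phenocopy wild type
while the double differs) reuse the same median threshold.  Valence
*inversion* is flagged when wild type and a single mutant both respond
significantly but with opposite signs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stats import DeltaDelta, EffectSize, PAdjustRecord

__all__ = [
    "ValenceCall",
    "DependenceCall",
    "RubricConfig",
    "classify_valence",
    "quartile_rubric",
    "classify_dependence",
    "detect_inversion",
    "DEPENDENCE_COMPARISONS",
]

#: canonical comparison keys for the dependence rubric
DEPENDENCE_COMPARISONS = (
    "tax4_vs_wt",
    "osm9_vs_wt",
    "double_vs_wt",
    "tax4_vs_double",
    "osm9_vs_double",
)


@dataclass
class ValenceCall:
    compound_id: str
    chemoactive: bool
    valence: str  # attractant | repellent | inactive
    vs_null_flags: dict[str, bool] = field(default_factory=dict)
    putative_false_positive: bool = False
    ambiguous: bool = False


@dataclass
class DependenceCall:
    compound_id: str
    dependence_class: str  # tax4_primary | osm9_primary | both_required | redundant | partial | unclassified
    inversion: bool = False
    quartile_bins: dict[str, int] = field(default_factory=dict)


@dataclass
class RubricConfig:
    """|DD| quartile edges; the median (second edge) is the call threshold."""

    median_threshold: float
    quartile_edges: tuple[float, float, float]

    def __post_init__(self) -> None:
        q1, q2, q3 = self.quartile_edges
        if not (q1 <= q2 <= q3):
            raise ValueError("quartile edges must be non-decreasing")
        if self.median_threshold != q2:
            raise ValueError("median_threshold must equal the second quartile edge")

    def bin_of(self, value: float) -> int:
        """Quartile bin index 0..3 for an |DD| value."""
        return int(np.searchsorted(self.quartile_edges, value, side="right"))


def classify_valence(
    effect_vs_dmso: EffectSize,
    effect_vs_water: EffectSize,
    padjust: PAdjustRecord | None = None,
    compound_id: str = "",
) -> ValenceCall:
    """Valence call for one compound from its two null-reference effects.

    Chemoactive iff at least one of the two CIs excludes zero; valence is the
    sign of the symmetric-DMSO mean difference.  If both comparisons are
    significant with conflicting signs the call is flagged ambiguous and the
    symmetric-DMSO sign wins.  ``padjust`` (the BH record of the compound's
    p-value) marks responses that lose significance after correction as
    putative false positives.
    """
    sig_dmso = effect_vs_dmso.significant
    sig_water = effect_vs_water.significant
    chemoactive = sig_dmso or sig_water
    ambiguous = (
        sig_dmso
        and sig_water
        and np.sign(effect_vs_dmso.mean_difference)
        * np.sign(effect_vs_water.mean_difference)
        < 0
    )
    if not chemoactive:
        valence = "inactive"
    elif effect_vs_dmso.mean_difference > 0:
        valence = "attractant"
    elif effect_vs_dmso.mean_difference < 0:
        valence = "repellent"
    else:  # zero point estimate yet significant vs water only
        valence = "attractant" if effect_vs_water.mean_difference > 0 else "repellent"
    putative_fp = bool(chemoactive and padjust is not None and not padjust.rejected)
    return ValenceCall(
        compound_id=compound_id,
        chemoactive=chemoactive,
        valence=valence,
        vs_null_flags={"DMSO:DMSO": sig_dmso, "DMSO:water": sig_water},
        putative_false_positive=putative_fp,
        ambiguous=bool(ambiguous),
    )


def quartile_rubric(abs_dd_values) -> RubricConfig:
    """Quartile edges of the pooled |DD| distribution.

    The pooled set should contain every compound x genotype-pair comparison
    computed in a run; the median becomes the substantial-vs-modest
    threshold of the dependence rubric.
    """
    vals = np.asarray(abs_dd_values, dtype=float).ravel()
    if vals.size < 4:
        raise ValueError("need at least 4 |DD| values for quartiles")
    q1, q2, q3 = np.percentile(vals, [25, 50, 75])
    return RubricConfig(median_threshold=float(q2), quartile_edges=(float(q1), float(q2), float(q3)))


def detect_inversion(
    wt_effect: EffectSize | None,
    mutant_effects: dict[str, EffectSize] | None,
) -> bool:
    """Valence flip: wild type and a single mutant significant, opposite signs."""
    if wt_effect is None or not mutant_effects:
        return False
    if not wt_effect.significant:
        return False
    for eff in mutant_effects.values():
        if eff.significant and np.sign(eff.mean_difference) * np.sign(
            wt_effect.mean_difference
        ) == -1:
            return True
    return False


def classify_dependence(
    dd: dict[str, float | DeltaDelta],
    rubric: RubricConfig,
    compound_id: str = "",
    wt_effect: EffectSize | None = None,
    mutant_effects: dict[str, EffectSize] | None = None,
) -> DependenceCall:
    """Channel-dependence class for one compound from its |DD| panel.

    ``dd`` maps comparison names (see :data:`DEPENDENCE_COMPARISONS`) to
    |DD| magnitudes (or :class:`DeltaDelta` objects, whose ``abs_value`` is
    used).  ``substantial`` means strictly above the rubric median; equal or
    below counts as modest.  Classes are checked in order: single-channel
    primary, both-required, redundant, partial; anything else is
    unclassified.
    """
    vals: dict[str, float] = {}
    for key in DEPENDENCE_COMPARISONS:
        if key not in dd:
            raise KeyError(f"missing comparison {key!r} for compound {compound_id!r}")
        v = dd[key]
        vals[key] = float(v.abs_value) if isinstance(v, DeltaDelta) else abs(float(v))

    m = rubric.median_threshold
    big = {k: v > m for k, v in vals.items()}

    if big["tax4_vs_wt"] and not big["tax4_vs_double"] and not big["osm9_vs_wt"]:
        cls = "tax4_primary"
    elif big["osm9_vs_wt"] and not big["osm9_vs_double"] and not big["tax4_vs_wt"]:
        cls = "osm9_primary"
    elif (
        big["tax4_vs_wt"]
        and big["osm9_vs_wt"]
        and not big["tax4_vs_double"]
        and not big["osm9_vs_double"]
    ):
        cls = "both_required"
    elif not big["tax4_vs_wt"] and not big["osm9_vs_wt"] and big["double_vs_wt"]:
        cls = "redundant"
    elif big["tax4_vs_wt"] and big["osm9_vs_wt"]:
        cls = "partial"
    else:
        cls = "unclassified"

    return DependenceCall(
        compound_id=compound_id,
        dependence_class=cls,
        inversion=detect_inversion(wt_effect, mutant_effects),
        quartile_bins={k: rubric.bin_of(v) for k, v in vals.items()},
    )
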