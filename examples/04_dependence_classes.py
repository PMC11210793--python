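"""Two-factor contrasts and channel-dependence classification.

Chemosensory transduction runs through the TAX-4 (CNG) and OSM-9 (TRPV) ion
channels.  Simulates two compounds — one whose response collapses in the
tax-4 mutant, one that collapses in osm-9 — computes each delta-delta panel
against wild type and the anosmic double mutant, pools all |DD| values into
the quartile rubric (as a real screen would, across every compound), and
classifies each compound's channel dependence.
"""

import chemotax as ct

# drift (mm) by strain, per compound: who still responds when a channel is lost
DRIFT = {
    "cinnamol-like (tax-4)": {"wt": 8.0, "tax4": 0.5, "osm9": 7.5, "double": 0.0},
    "octanol-like (osm-9)": {"wt": -7.0, "tax4": -6.5, "osm9": -0.5, "double": 0.0},
    "limonin-like (either)": {"wt": 6.0, "tax4": 3.0, "osm9": 3.0, "double": 0.0},
}

PAIRS = {
    "tax4_vs_wt": ("tax4", "wt"),
    "osm9_vs_wt": ("osm9", "wt"),
    "double_vs_wt": ("double", "wt"),
    "tax4_vs_double": ("tax4", "double"),
    "osm9_vs_double": ("osm9", "double"),
}


def draw(mu, seed):
    return ct.sample_endpoint_positions(
        ct.PositionModel(drift_mu=mu, spread_sigma=9.0, n_worms=600, seed=seed)
    ).z


panels = {}
for ci, (compound, drift) in enumerate(DRIFT.items()):
    samples = {
        (s, cond): draw(drift[s] if cond == "test" else 0.0, seed=100 * ci + i)
        for i, (s, cond) in enumerate(
            (s, c) for s in drift for c in ("control", "test")
        )
    }
    panels[compound] = {
        name: ct.delta_delta(
            samples[(a, "control")], samples[(a, "test")],
            samples[(b, "control")], samples[(b, "test")],
            n_resamples=5000, seed=3, label=f"{compound}|{name}",
        )
        for name, (a, b) in PAIRS.items()
    }

# the rubric pools |DD| over every compound x genotype-pair comparison
rubric = ct.quartile_rubric(
    [dd.abs_value for panel in panels.values() for dd in panel.values()]
)
print(f"pooled |DD| rubric median: {rubric.median_threshold:.2f} mm\n")

for compound, panel in panels.items():
    for name, dd in panel.items():
        print(f"  {name:16s} DD = {dd.delta_delta:+6.2f} mm  |DD| = {dd.abs_value:5.2f}")
    call = ct.classify_dependence(panel, rubric, compound_id=compound)
    print(f"{compound}: {call.dependence_class}\n")
# tax4_primary: losing tax-4 changes the response a lot (vs wild type) but the
# tax-4 mutant behaves like the anosmic double, while osm-9 barely matters;
# osm9_primary is the mirror image.  The third compound keeps most of its
# response in either single mutant yet loses it in the double — the channels
# serve it redundantly.
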