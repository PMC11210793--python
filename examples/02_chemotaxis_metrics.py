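"""Score an endpoint assay: gradient coordinates, index, mean position.

Draws endpoint positions from a drift model (worms attracted 7.5 mm toward
the test compound on average), converts pixel positions through the measured
arena geometry, and computes the two per-arena metrics.
"""

import numpy as np

import chemotax as ct

model = ct.PositionModel(drift_mu=7.5, spread_sigma=10.0, n_worms=250, seed=4)
positions = ct.sample_endpoint_positions(model)

# pixel -> mm mapping at the nominal geometry (w = 3,041 px at 1,200 dpi)
geom = ct.ArenaGeometry(w=3041, dpi=1200)
x_px = geom.w / 2 - positions.z * geom.dpi / 25.4  # px from the test apex
round_trip = ct.to_gradient_coords(x_px, geom)
assert np.allclose(round_trip.z, positions.z)

res = ct.chemotaxis_index(positions, w_mm=65.0)
summary = ct.summarize_arena(positions, geom, compound_id="attractant demo")

print(f"n worms:            {positions.n}")
print(f"p (test side):      {res.p_count}")
print(f"q (control side):   {res.q_count}")
print(f"chemotaxis index:   {res.index:+.3f}")
print(f"mean position:      {ct.mean_position(positions):+.2f} mm")
print(f"QC (>=150 worms):   {'pass' if summary.qc_pass else 'fail'}")
# A positive index and positive mean position both say the population shifted
# toward the test compound; worms in the central ninth (starting zone) count
# for the mean but are excluded from the index.
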