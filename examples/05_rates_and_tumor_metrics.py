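"""Closed-form study metrics: exchange fluxes, doubling time, tumor growth.

A culture doubling in 24 h consumes 0.6 umol of a metabolite from the
medium; the per-cell flux follows from the exponential-growth model.
Caliper measurements convert to ellipsoid volumes and a treated/control
growth-inhibition percentage.
"""

import qm2ta as q

assay = q.GrowthAssay(n0=1e5, nt=2e5, m0=2.0, mt=1.4, duration=24.0)
j, mu = q.exchange_rate(assay)
print(f"growth rate mu = {mu:.6f} / h -> doubling time {q.doubling_time(mu):.1f} h")
print(f"net exchange flux J = {j:.4g} umol / cell / h (negative = consumption)")

volume = q.ellipsoid_volume(q.TumorMeasurement(length=10.0, width=6.0))
print(f"10 x 6 mm tumor volume: {volume:.2f} mm^3")

inhibition = q.tgi(v_t_t=2.0, v_t_0=1.0, v_c_t=4.0, v_c_0=1.0)
print(f"TGI (treated doubled, control quadrupled): {inhibition:.0f}%")

activity = q.enzyme_activity_proxy(product_levels=4.0, substrate_levels=2.0,
                                   control_ratio=2.0)
print(f"enzyme activity proxy (product/substrate vs control): {activity:.1f}")
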