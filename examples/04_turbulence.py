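"""Turbulence-like dynamics of simulated BOLD.

Simulates the model at two coupling strengths, extracts instantaneous
phases of the band-limited BOLD, computes the local Kuramoto order
parameter with the exponential spatial kernel (lambda = 0.18/mm), and
reports the turbulence level D = std of the local synchronization over
regions and time.
"""

import dmfsim as d

params = d.DMFParameters()
hemo = d.HemodynamicParameters()

coords = d.make_coordinates(20, geometry="box", scale=30.0, seed=2)
conn = d.make_connectome(
    d.ConnectomeSpec(n_regions=20, model="modular",
                     target_mean_strength=0.5, seed=1),
    coordinates=coords)
beta = d.node_strength(conn)

for G in (0.0, 1.5):
    J = d.linear_fic(G, beta, 0.75)
    res = d.run_simulation(params, hemo, conn, d.CouplingConfig(G=G, J=J),
                           d.IntegrationConfig(duration=210.0, seed=7))
    D = d.turbulence_from_bold(res.bold, coords)
    print(f"G={G}: turbulence level D = {D:.4f}")

print("Higher coupling increases the spatiotemporal variability of local "
      "synchronization, raising D; an uncoupled network shows only "
      "noise-level variability.")
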