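"""Why the oscillatory modification is needed for a Lagrangian description.

First the failure: differentiating the real first-order equation dz/dt = az+d
once gives a second-order equation with a Lagrangian, but that equation has a
two-constant solution family z = k1 e^{at} + k2 e^{-at} - d/a of which only
the k2 = 0 members solve the original dynamics — stationary action cannot
recover the first-order flow uniquely. Then the success: trajectories of the
complex equation i dz/dt = Az (Hermitian A) make the action stationary, have
vanishing Euler-Lagrange residual, and a pointwise-zero real Lagrangian.
"""

import numpy as np

import neulag as nl

# --- the real-variable dead end -------------------------------------------
a, d = 0.8, 0.6
emb = nl.second_order_embedding([[a]], [d])
print(f"embedding of dz/dt = {a} z + {d}:  E = {emb.E[0,0]}, f = {emb.f[0]:.3f}")
for k1, k2 in [(1.0, 0.0), (1.0, 1.0)]:
    r = nl.spurious_solution_residual(a, d, k1, k2, t=0.5)
    print(f"  first-order residual of (k1={k1}, k2={k2}) branch at t=0.5: {r:+.4f}")
print("-> the k2 branch solves the embedded equation but not the dynamics.")

# --- the complex oscillatory equation passes every variational check -------
spec = nl.make_three_node_network(variant="modified").with_(non_dissipative=True)
traj = nl.simulate_modified(spec, np.array([1.0, 0.5j, -0.2]), None,
                            nl.NoiseSpec(), T=1025, dt=0.002)
rep = nl.mechanics_report(traj, spec)
first, second = nl.action_stationarity_check(traj, spec, perturbation_scale=1e-3, seed=0)
print(f"on-shell:  max |L(t)| = {np.max(np.abs(rep.lagrangian)):.2e}, "
      f"action S = {rep.action:.2e}")
print(f"           max Euler-Lagrange residual = {np.max(np.abs(rep.el_residual)):.2e}")
print(f"           action variation: first-order {first:.2e} << second-order {second:.2e}")

# a decaying original-equation trajectory is NOT stationary for this action
orig = nl.simulate_original(nl.make_three_node_network(),
                            np.array([1.0, 0.5, -0.2], dtype=complex), None,
                            nl.NoiseSpec(), T=1025, dt=0.002)
off = nl.Trajectory(orig.times, orig.states, orig.observations)
f_off, s_off = nl.action_stationarity_check(off, spec, perturbation_scale=1e-3, seed=0)
print(f"off-shell: first-order {f_off:.2e} (non-stationary, as it must be)")
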