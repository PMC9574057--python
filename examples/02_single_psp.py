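"""Unit-PSP calibration of the current-jump factor alpha.

Efficacies J are peak postsynaptic-potential amplitudes in mV, but the
exponential-current synapse injects charge.  The factor alpha converts
between the two: a spike through a synapse of efficacy J makes the current
jump by alpha*J/tau_syn, which peaks the membrane at exactly J mV.  This
script verifies the contract by brute-force simulation on a fine grid.
"""

from synwm import NeuronParams, NeuronState, alpha_factor, make_propagator, psp_peak_time, step_neuron

params = NeuronParams(tau_m=15.0, tau_exc=2.0, V_th=1e9, V_reset=-1.0)
alpha = alpha_factor(params, params.tau_exc)
print(f"alpha(tau_m=15 ms, tau_syn=2 ms) = {alpha:.4f} (current units per mV)")
print(f"predicted peak time = {psp_peak_time(15.0, 2.0):.3f} ms")

J = 1.0
dt = 0.001
prop = make_propagator(params, dt)
state = NeuronState(I_exc=alpha * J / params.tau_exc)
t, vmax, tmax = 0.0, 0.0, 0.0
for _ in range(int(15.0 / dt)):
    state, _ = step_neuron(state, prop, 0.0, params, t)
    t += dt
    if state.V > vmax:
        vmax, tmax = state.V, t
print(f"simulated peak: {vmax:.6f} mV at {tmax:.3f} ms (target: {J} mV)")
print("-> the jump alpha*J/tau_syn reproduces a J-mV PSP, so network "
      "efficacies can be stated in millivolts.")
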