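"""Build a ground-state free-energy profile and read off the energetics.

Samples the two-state linear-response surrogate (λ = 40, ΔG₀ = 5 kcal/mol)
over the default 26-window mapping schedule, accumulates the mapping free
energies, reweights every frame onto the energy-gap coordinate, and
extracts the stationary points.  The printed values should match the
Marcus closed forms: ΔG‡ = (λ+ΔG₀)²/(4λ) = 12.66, ΔG₀ = 5, λ = 40.
"""

from evbscreen import (
    EVBParameters,
    SurrogateModel,
    analytic_truth,
    analyze_frames,
    default_schedule,
    run_evb_protocol,
)

model = SurrogateModel.from_targets(lam=40.0, dG0=5.0)
schedule = default_schedule()
params = EVBParameters()  # alpha = 0, H12 = 0, 300 K

frames = run_evb_protocol(model, schedule, params,
                          n_steps_per_window=20000, seed=1)
result, profile = analyze_frames(frames, params, schedule, bins=100)

truth = analytic_truth(model)
print(f"frames analyzed:        {result.n_frames}")
print(f"activation free energy: {result.dG_act:6.2f} kcal/mol "
      f"(closed form {truth.diabatic_barrier:.2f})")
print(f"reaction free energy:   {result.dG_rxn:6.2f} kcal/mol "
      f"(closed form {truth.dG0:.2f})")
print(f"reorganization energy:  {result.lambda_est:6.2f} kcal/mol "
      f"(closed form {truth.lam:.2f})")
print(f"stationary points on the gap: reactant {result.x_rs:.1f}, "
      f"barrier {result.x_ts:.1f}, product {result.x_ps:.1f}")
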