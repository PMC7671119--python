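"""Evaluate external-marker strain tracking against an internal reference.

Seven simulated feeding strikes are measured by two methods at once: the
internal (reference) strain and skin-mounted external markers whose
strain is attenuated by a skin-slip coupling of 0.90 plus 0.5% strain
measurement noise.  Per-strike regressions of external on internal strain
give the method's accuracy (slope vs the ideal 1) and precision (residual
RMSE).
"""

from vromm import run_validation_experiment

report = run_validation_experiment(
    n_trials=7, skin_slip_alpha=0.90, strain_noise_sd_pct=0.5, seed=4
)
print(report.per_trial[["slope", "intercept", "rmse_pct"]].round(4).to_string(index=False))
print()
print(f"accuracy (mean slope ratio): {report.mean_accuracy:.3f} "
      f"+/- {report.sem_accuracy:.3f} (SEM, n={report.n_trials})")
print(f"precision (mean residual RMSE): {report.mean_rmse_pct:.3f} "
      f"+/- {report.sem_rmse_pct:.3f} % strain")
print(f"underestimation margin: {report.underestimation_margin_pct:.1f}%")
print()
print("-> a slope below 1 means external markers underestimate true strain")
print("   (skin slip); the recovered accuracy matches the simulated 0.90")
print("   coupling and the RMSE matches the injected 0.5% noise.")
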