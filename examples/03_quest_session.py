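"""Run an adaptive (QUEST) session against a simulated observer.

Each condition keeps its own posterior over candidate bisection points;
every trial is placed at the perturbed posterior mode (easy trials near an
anchor), so sampling concentrates where it is most informative.  The final
estimates come from refitting the full trial log, not from the adaptive
track itself.
"""

import numpy as np

from tempobind import (
    Condition,
    ObserverParams,
    QuestConfig,
    SessionConfig,
    fit_subject,
    run_session,
)

observer = ObserverParams(sigma_a=100.0, sigma_v=200.0, bias_a=0.0, bias_v=0.0)
records = run_session(
    observer,
    SessionConfig(seed=3),
    QuestConfig(prior_mean=500, prior_sd=300, assumed_sigma=150),
    rng=np.random.default_rng(3),
    subject_id="S01",
)
print(f"trials run: {len(records)}, "
      f"easy fraction: {np.mean([r.is_easy for r in records]):.2f}")

audio_probes = [r.probe_nominal for r in records
                if r.condition is Condition.A and not r.is_easy]
print(f"audio regular-trial probes: first 3 = "
      f"{[f'{p:.0f}' for p in audio_probes[:3]]}, "
      f"last 3 = {[f'{p:.0f}' for p in audio_probes[-3:]]} (homing in on 500)")

fits = fit_subject(records, n_boot=100, rng=np.random.default_rng(4))
print("\nper-condition fits (true audio sigma 100, visual 200, PSE 500):")
for cond, est in fits.items():
    print(f"  {cond:10s} PSE {est.pse:6.1f} +/- {est.se_pse:5.1f} ms   "
          f"sigma {est.sigma:6.1f} +/- {est.se_sigma:5.1f} ms")
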