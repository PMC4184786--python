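"""Measure pulse-chase cluster growth on rendered two-channel image pairs.

Renders 99 cluster pairs whose green (old + new protein) disk is 16% larger
than the red (old protein) core, with Poisson noise, then sizes both channels
by FWHM and summarises the relative increase (d_g - d_r) / d_r.  A control
with zero shell growth mimics adding both ligands simultaneously.
"""

import dataclasses

from erclust import morphometry as mm
from erclust import synth


def measure(growth: float, base_seed: int) -> mm.GrowthSummary:
    cfg = synth.ImageSimConfig(
        core_diameter=1.0,
        shell_growth_fraction=growth,
        peak_intensity=1000.0,
        background=10.0,
        noise_model="poisson",
    )
    records = []
    for i, seed in enumerate(synth.derive_seeds(base_seed, 99)):
        img, gt = synth.render_cluster_pair(dataclasses.replace(cfg, seed=seed))
        records.append(
            mm.measure_cluster(img, (gt.x_um[0], gt.y_um[0]), cluster_id=i, cell_id=i % 9)
        )
    return mm.summarize_growth(records)


pulse_chase = measure(0.16, base_seed=2)
control = measure(0.0, base_seed=3)

print(f"sequential ligands : {100 * pulse_chase.mean_rel_increase:.1f}% "
      f"± {100 * pulse_chase.sem_rel_increase:.2f}% (SEM, n = {pulse_chase.n_clusters})")
print(f"simultaneous (ctrl): {100 * control.mean_rel_increase:.2f}% "
      f"± {100 * control.sem_rel_increase:.2f}% (SEM, n = {control.n_clusters})")
print()
print("The pulse-chase arm should recover ~16% growth; the control should be")
print("indistinguishable from zero — no measurable size difference.")
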