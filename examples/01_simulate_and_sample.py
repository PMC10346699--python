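"""Generate a root system, build the probe sampling plan, and sense roots.

The probe samples a 50 mm-radius, 100 mm-deep soil cylinder around the stem.
At full scale the plan holds 130 tunnels x 35 viewpoints = 4550 camera
positions per plant; here we also build a reduced 20 x 10 desk-scale plan.
"""

import numpy as np

from rhizoprobe import SceneConfig, generate_root_system, generate_sampling_plan, sense_roots

full = SceneConfig()
plan_full = generate_sampling_plan(full, seed=1)
print(f"full design: {plan_full.n_viewpoints} viewpoints "
      f"({full.n_tunnels} tunnels x {full.viewpoints_per_tunnel})")

desk = SceneConfig(n_tunnels=20, viewpoints_per_tunnel=10)
plan = generate_sampling_plan(desk, seed=1)
system = generate_root_system(desk, group="control", plant_seed=42, plant_id=0)
n_thin = sum(s.true_class == "thin" for s in system.segments)
n_thick = len(system.segments) - n_thin
print(f"desk plant: {n_thin} thin and {n_thick} thick root segments")

visible = sense_roots(plan, system, desk.sense_radius)
n_obs = sum(len(v) for v in visible)
n_empty = sum(len(v) == 0 for v in visible)
print(f"sensing at {desk.sense_radius} mm: {n_obs} root sightings over "
      f"{plan.n_viewpoints} viewpoints ({n_empty} viewpoints see nothing)")
# Each sighting becomes one 3D-tagged observation; empty frames mirror the
# many root-free images a real in-soil probe collects.
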