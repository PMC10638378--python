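"""Compare TSDPSO with standard PSO on a multimodal benchmark.

Runs both optimizers on the 10-D Rastrigin function over ten paired
seeds and prints the median final fitness of each.  Rastrigin has many
local minima; the switching-delay and traction mechanisms should let
TSDPSO escape basins the fixed-inertia standard swarm gets stuck in, so
its median should be much closer to the global optimum of 0.
"""

import numpy as np

from tsdpso import ObjectiveSpec, SwarmConfig, optimize_standard_pso, optimize_tsdpso

objective = ObjectiveSpec.from_benchmark("rastrigin", dimension=10)

tsdpso_final, standard_final = [], []
for seed in range(10):
    config = SwarmConfig(seed=seed, convergence_tolerance=1e-12)
    tsdpso_final.append(optimize_tsdpso(objective, config).gbest_fitness)
    standard_final.append(optimize_standard_pso(objective, config).gbest_fitness)

print(f"TSDPSO        median final fitness: {np.median(tsdpso_final):8.3f}")
print(f"standard PSO  median final fitness: {np.median(standard_final):8.3f}")
print("Lower is better; the global optimum of Rastrigin is 0.")
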