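"""Run one social-learning simulation and inspect its generative output.

A single tool-using seed agent is placed among 99 naive agents on a 20x20
grid; every co-occupancy with a tool user raises a naive adult's acquisition
probability by 1%. The run stops once half the population uses tools.
"""

from tooltrans import SimConfig, run_simulation

config = SimConfig(condition="social", rng_seed=7)
log, meta = run_simulation(config)

print(f"terminated by {meta.terminated_by} after {meta.steps} steps")
print(f"tool users: {int(log.agents.tool_user.sum())} of {len(log.agents)}")
print(f"association records: {len(log.records)}")
print(log.agents.head().to_string(index=False))

# Each record row is one unordered pair sharing a grid cell at one step;
# the record count is what weights the association network downstream.
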