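"""Generate synthetic focal-follow data and push it through the pipeline.

Emulates a shoreline focal-follow season: 69 individuals, 42 mature with
known tool-user status, 5990 directed 1 m proximity scans. A positive
assortativity tilts tool users toward each other, planting the
social-transmission signature the analysis is meant to detect.
"""

from tooltrans import (
    ObsConfig,
    build_design,
    build_network,
    fit_model,
    generate_observational,
    node_metrics,
    summarize_posterior,
)

records, attrs = generate_observational(ObsConfig(assortativity=1.0, rng_seed=3))
print(f"{len(records)} scans over {len(attrs)} individuals "
      f"({int(attrs.mature.sum())} mature, {int(attrs.tool_user.sum())} tool users)")

G = build_network(records, attrs, directed=True)
metrics = node_metrics(G)
data = build_design(attrs, metrics, age_threshold=None, mature_col="mature")
post = fit_model(data, chains=2, draws=500, seed=3)

summary = summarize_posterior(post)
strength_rows = summary[summary.parameter.str.startswith("strength (adult")]
print(strength_rows.round(3).to_string(index=False))
# Positive adult strength slopes recover the planted assortativity: mature
# individuals tied strongly to tool users are likelier to be tool users.
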