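# Blueprint file schema

A blueprint is a JSON document (extension-agnostic) describing a model as
a graph of components.  The canonical form — what `serialize_blueprint`
emits and what round-trips byte-for-byte — has sorted keys, sorted edges,
two-space indentation, and `repr`-formatted floats.

Top-level fields (all required except `metadata`; unknown fields are an
error, never silently ignored):

```json
{
  "version": "1",
  "nodes": {
    "<node id>": {"kind": "<component kind>", "params": { ... }},
    ...
  },
  "edges": [
    {"source": "<node id>", "source_port": "<port>",
     "target": "<node id>", "target_port": "<port>"},
    ...
  ],
  "metadata": {"dt": "1.0", "description": "..."}
}
```

* `version` — schema version string; a mismatch is an explicit error.
* `metadata.dt` — integration step in ms (string-valued like all
  metadata); default `"1.0"`.
* Node ids must be unique; every edge must reference existing nodes and
  ports with matching sizes.  Multiple edges into one input port sum.
* Input ports with no incoming edge become the model's external inputs;
  output ports never consumed become its outputs.

## Registered component kinds

| kind | params (defaults) | in ports | out ports |
|---|---|---|---|
| `lif_pool` | `n`, plus any LIF constant (`tau_m` 20, `v_rest` -65, `R` 1, `theta_base` -50, `a` 2, `tau_th` 50, `r_spike` 5, `v_reset` -65) | `current` (n) | `spikes` (n) |
| `adex_pool` | `n`, plus AdEx constants (regular-spiking defaults) | `current` (n) | `spikes` (n) |
| `hh_pool` | `n`, plus HH constants (squid-axon defaults) | `current` (n) | `spikes` (n) |
| `traced_synapse` | `n_pre`, `n_post`, `tau_s` 5, `density` 0.1, `w_min` 0, `w_max` 1, `sign` +1/-1, `d_max_ms` 10, `exclude_self` false, `plastic` false, `plasticity` {...} | `spikes` (n_pre); `post_spikes` (n_post, plastic only) | `current` (n_post) |
| `topological_spiker` | `n_units` 32, `value_range` [[lo,hi],...], `topology` ["line"\|"circle",...], `sigma` 0.1, `rate_max` 0.5 | `value` (n_dims) | `spikes` (n_dims*n_units) |
| `trace_integrator` | `k` 2, `pool_sizes` [...], `tau_out` 50, `gain` 0.3 | `spikes0..spikes{k-1}` | `traces` (k) |

The `plasticity` block of a plastic `traced_synapse` takes the
`PlasticityParams` fields: `eta`, `alpha`, `beta`, `gamma`, `delta`,
`tau_pre`, `tau_post`, `w_min`, `w_max`, `prune_eps`, `growth_prob`,
`growth_w`.

`snnkit.cartpole_blueprint()` builds the repository's reference agent
blueprint (two motor pools with mutual inhibition); serialize it to see
a complete example:

```python
from snnkit import cartpole_blueprint, serialize_blueprint
print(serialize_blueprint(cartpole_blueprint()))
```
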