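# Scenario file schema

Scenario tables are CSV (one row per scenario) or JSON (a list of objects
with the same keys).

| column           | type   | description                                                        |
|------------------|--------|--------------------------------------------------------------------|
| `scenario_id`    | string | unique label                                                       |
| `study`          | string | free-form grouping tag                                             |
| `predecessors`   | string | semicolon-separated `RANK:DECISION` tokens, in decision order      |
| `private_signal` | string | `a` or `b` — the focal actor's own signal                          |
| `reliability`    | number | `p(a|A) = p(b|B)`; decimal or exact fraction such as `2/3`         |
| `prior_A`        | number | a-priori probability of option A                                   |

Rank tokens: `EQ` (equally ranked peer) and `HR` (higher-ranked
authority).  Decisions: `A` or `B`.  An empty `predecessors` field means
the focal actor decides first.

The packaged fixtures `study1` (12 urn tasks, all `EQ`) and `study2`
(40 clinical scenarios mixing `EQ` and `HR`) follow this schema with
reliability 2/3 and prior 0.5.  Loaders reject rows with more than three
predecessors unless relaxed with `max_predecessors=None`.
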