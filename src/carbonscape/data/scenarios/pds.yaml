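# Planned development: trade-off scenario. Ecological barriers freeze
# forests/wetland/waters, agricultural zones freeze farmland,
# planned-development zones are favored for construction, and per-class
# conversion outside restrictions is capped at a 6.9% development
# intensity.
name: pds
demand: markov
multipliers: []
restrictions:
  - mask: ecological_barrier
    classes: [forests, wetland, waters]
  - mask: agricultural_zone
    classes: [farmland]
planned_development: {mask: planned_development, factor: 1.5}
intensity_cap: 0.069
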