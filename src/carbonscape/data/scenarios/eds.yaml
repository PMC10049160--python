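# Economic development: production and living land favored; all classes
# except waters convert more readily to farmland and construction;
# planned-development zones favored; existing waters frozen to secure
# supply.
name: eds
demand: markov
multipliers:
  - from: [farmland, forests, grassland, wetland, construction, unused]
    to: [farmland, construction]
    factor: 1.5
restrictions:
  - {freeze_class: waters}
planned_development: {mask: planned_development, factor: 1.5}
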