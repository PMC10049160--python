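# Ecological protection: restoration conversions boosted, urbanization of
# farmland/unused land cut, ecological classes frozen inside barrier zones
# (except within 10 km of existing urban areas, left free for minimum
# urbanization demand).
name: eps
demand: markov
multipliers:
  - {from: [farmland, unused], to: [forests, wetland, waters], factor: 1.6}
  - {from: [grassland], to: [forests], factor: 1.6}
  - {from: [farmland, unused], to: [construction], factor: 0.2}
restrictions:
  - mask: ecological_barrier
    classes: [forests, grassland, wetland, waters]
    exempt_buffer: {class: construction, radius_m: 10000}
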