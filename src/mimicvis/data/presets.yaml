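# Visual-system preset table: receptor channels (short -> long lambda-max),
# relative cone/photoreceptor abundances (eta), and Weber fraction of the
# most abundant channel. Cone proportions follow the published retinal
# counts for each observer; lambda-max values not measured for these
# observers are editable defaults, not claims.
bluetit-uvs:
  description: Blue tit (Cyanistes caeruleus), ultraviolet-sensitive avian system
  weber: 0.05
  achromatic:
    name: double
    lambda_max: 563
    weber: 0.05
  channels:
    - {name: UV, lambda_max: 371, eta: 0.37}
    - {name: SW, lambda_max: 448, eta: 0.71}
    - {name: MW, lambda_max: 503, eta: 0.99}
    - {name: LW, lambda_max: 563, eta: 1.0}
peafowl-vs:
  description: Peafowl (Pavo cristatus), violet-sensitive avian system
  weber: 0.05
  achromatic:
    name: double
    lambda_max: 605
    weber: 0.05
  channels:
    - {name: V, lambda_max: 432, eta: 0.45}
    - {name: SW, lambda_max: 477, eta: 0.86}
    - {name: MW, lambda_max: 537, eta: 1.0}
    - {name: LW, lambda_max: 605, eta: 0.95}
erato-female-green:
  description: Heliconius erato female, green long-wavelength receptor (no red filtering)
  weber: 0.05
  channels:
    - {name: UV1, lambda_max: 355, eta: 0.086}
    - {name: UV2, lambda_max: 398, eta: 0.076}
    - {name: B, lambda_max: 470, eta: 0.17}
    - {name: LW, lambda_max: 555, eta: 1.0}
erato-female-red:
  description: Heliconius erato female, red-shifted long-wavelength receptor (filtering pigments)
  weber: 0.05
  channels:
    - {name: UV1, lambda_max: 355, eta: 0.086}
    - {name: UV2, lambda_max: 398, eta: 0.076}
    - {name: B, lambda_max: 470, eta: 0.17}
    - {name: LW, lambda_max: 600, eta: 1.0}
erato-male-green:
  description: Heliconius erato male, green long-wavelength receptor
  weber: 0.05
  channels:
    - {name: UV2, lambda_max: 398, eta: 0.13}
    - {name: B, lambda_max: 470, eta: 0.2}
    - {name: LW, lambda_max: 555, eta: 1.0}
erato-male-red:
  description: Heliconius erato male, red-shifted long-wavelength receptor
  weber: 0.05
  channels:
    - {name: UV2, lambda_max: 398, eta: 0.13}
    - {name: B, lambda_max: 470, eta: 0.2}
    - {name: LW, lambda_max: 600, eta: 1.0}
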