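# Default variable system for granular-activated-carbon drinking-water
# biofilters.  `scale` and `offset` convert raw file values into the
# canonical unit: canonical = raw * scale + offset (e.g. Celsius inputs
# would use offset: 273.15; millimetre inputs scale: 0.001).  The
# packaged default assumes files already carry canonical units.
#
# `repeating` names the characteristic-scale variables preferred as
# pivots when solving for the dimensionless groups: the filter-bed
# diameter (geometry), the filter age (time scale), the water
# temperature, and the influent carbon concentration.
repeating: [T, A, IC_org, C_fit]
variables:
  T:
    description: water temperature at the sampling location
    role: independent
    unit: K
    dimensions: {temperature: 1}
  Pz:
    description: characteristic pore size of the filter medium
    role: independent
    unit: m
    dimensions: {length: 1}
  A:
    description: filter age since start of operation
    role: independent
    unit: s
    dimensions: {time: 1}
  IC_org:
    description: influent organic carbon concentration
    role: independent
    unit: g/m^3
    dimensions: {mass: 1, length: -3}
  EC_org:
    description: effluent organic carbon concentration (predicted quantity)
    role: dependent
    unit: g/m^3
    dimensions: {mass: 1, length: -3}
  Bt:
    description: empty bed contact time
    role: independent
    unit: s
    dimensions: {time: 1}
  P:
    description: mean GAC particle diameter
    role: independent
    unit: m
    dimensions: {length: 1}
  C_fit:
    description: filter bed diameter
    role: independent
    unit: m
    dimensions: {length: 1}
  t0:
    description: ambient air temperature
    role: independent
    unit: K
    dimensions: {temperature: 1}
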