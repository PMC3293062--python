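# Printed group summary statistics (mean, SE; n = 10 animals per group) of
# the six-arm cisplatin / Ginkgo biloba rat study the generators emulate.
# Units: Testis W, Epidid. W in g; SpC in 10^6/g cauda; SpM in %;
# MDA in nmol/mg protein; MPO in mu/mg protein; CAT, SOD in u/mg protein.
#
# Two entries repair obvious typography in the printed tables:
#   CIS+H SpC printed "118.78 +/- .8.78"  -> SE 8.78
#   CIS   MDA printed "1.2 +/- 008"       -> SE 0.08
#   CIS+H SOD printed "3.25 +/- .0.06"    -> SE 0.06
n_animals: 10
indicators: ["Testis W", "Epidid. W", "SpC", "SpM", "MDA", "MPO", "CAT", "SOD"]
groups:
  N:
    "Testis W":  {mean: 3.51,   se: 0.06}
    "Epidid. W": {mean: 1.64,   se: 0.06}
    "SpC":       {mean: 131.0,  se: 7.73}
    "SpM":       {mean: 79.125, se: 3.34}
    "MDA":       {mean: 0.97,   se: 0.03}
    "MPO":       {mean: 16.92,  se: 0.34}
    "CAT":       {mean: 146.79, se: 2.9}
    "SOD":       {mean: 3.37,   se: 0.02}
  GB:
    "Testis W":  {mean: 3.59,   se: 0.11}
    "Epidid. W": {mean: 1.53,   se: 0.06}
    "SpC":       {mean: 134.9,  se: 11.64}
    "SpM":       {mean: 68.12,  se: 2.64}
    "MDA":       {mean: 0.86,   se: 0.08}
    "MPO":       {mean: 17.13,  se: 0.31}
    "CAT":       {mean: 144.07, se: 2.03}
    "SOD":       {mean: 3.37,   se: 0.01}
  CIS:
    "Testis W":  {mean: 2.99,   se: 0.12}
    "Epidid. W": {mean: 1.30,   se: 0.04}
    "SpC":       {mean: 83.94,  se: 8.03}
    "SpM":       {mean: 28.125, se: 1.52}
    "MDA":       {mean: 1.2,    se: 0.08}
    "MPO":       {mean: 24.65,  se: 2.2}
    "CAT":       {mean: 84.89,  se: 3.24}
    "SOD":       {mean: 3.62,   se: 0.05}
  CIS+L:
    "Testis W":  {mean: 3.49,   se: 0.08}
    "Epidid. W": {mean: 1.38,   se: 0.05}
    "SpC":       {mean: 94.50,  se: 20.25}
    "SpM":       {mean: 54.0,   se: 5.59}
    "MDA":       {mean: 1.0,    se: 0.07}
    "MPO":       {mean: 18.88,  se: 0.93}
    "CAT":       {mean: 127.9,  se: 3.9}
    "SOD":       {mean: 3.26,   se: 0.08}
  CIS+M:
    "Testis W":  {mean: 3.52,   se: 0.18}
    "Epidid. W": {mean: 1.46,   se: 0.08}
    "SpC":       {mean: 94.67,  se: 7.77}
    "SpM":       {mean: 49.0,   se: 3.83}
    "MDA":       {mean: 0.84,   se: 0.06}
    "MPO":       {mean: 19.69,  se: 1.54}
    "CAT":       {mean: 118.0,  se: 3.64}
    "SOD":       {mean: 3.16,   se: 0.09}
  CIS+H:
    "Testis W":  {mean: 3.65,   se: 0.13}
    "Epidid. W": {mean: 1.44,   se: 0.05}
    "SpC":       {mean: 118.78, se: 8.78}
    "SpM":       {mean: 50.0,   se: 4.2}
    "MDA":       {mean: 0.98,   se: 0.05}
    "MPO":       {mean: 16.93,  se: 0.59}
    "CAT":       {mean: 134.4,  se: 1.88}
    "SOD":       {mean: 3.25,   se: 0.06}
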