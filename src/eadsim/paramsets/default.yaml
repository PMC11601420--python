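# Calibrated ventricular myocyte parameters, normal Ca-induced inactivation
# (ACa = 0.15).  Units: ms, mV, uM (Ca), mM (Na/K), uA/uF.
# Phenomenological constants were fixed by calibrating against steady-state
# APD90 statistics at CL = 500 ms with Nb = 4000 junctional clusters and the
# EAD onset of the reduced-inactivation variant (see docs/methods.md).
frt: 0.03767
nao: 136.0
ko: 5.4
cao: 1.8
ki: 140.0
gna: 12.0
gkr: 0.024
gks: 1.0
gk1: 0.3
gtos: 0.04
gtof: 0.11
gnak: 1.5
gnaca: 60000.0
gca: 100.0
xs2mult: 4.0
knai: 12.0
eta: 0.35
ksat: 0.1
kmna: 87.5
kmca: 1.38
callo: 0.3
r1: 0.3
r2: 3.0
a24o: 0.002
a34o: 0.002
aca: 0.15
cth: 0.3
k42o: 0.00365
k42v: 0.02
v42: -30.0
s42: 6.0
a45: 0.004
k54: 0.00465
v54: -55.0
s54: 6.0
lcc_couple_all: 1
nbtot: 4000
betab: 0.0333333333
alpha0: 0.35
ksr: 500.0
gb: 0.11428571
vup: 0.4
kup: 0.5
tauc: 5.0
tausr: 50.0
vb: 1.0
vi: 9.0
vsrb: 0.35
vsri: 3.15
bufc: 0.1
bufsr: 1.0
gri: 0.0
cith: 1.0
sca: 10.0
snaca: 2.0
conv_na: 6.0e-06
nai_clamped: 1
stim_amp: -80.0
stim_dur: 1.0
dtmin: 0.01
dtmax: 0.1
dvdt_switch: 1.0
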