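# Working-memory subnetwork: 14 Desikan-Killiany regions per hemisphere
# (prefrontal, posterior parietal, anterior cingulate, entorhinal groups).
# Edit this list to change the default subnetwork used for pathlength.
lh-caudalanteriorcingulate
lh-caudalmiddlefrontal
lh-entorhinal
lh-inferiorparietal
lh-lateralorbitofrontal
lh-medialorbitofrontal
lh-parsopercularis
lh-parsorbitalis
lh-parstriangularis
lh-precuneus
lh-rostralanteriorcingulate
lh-rostralmiddlefrontal
lh-superiorfrontal
lh-superiorparietal
rh-caudalanteriorcingulate
rh-caudalmiddlefrontal
rh-entorhinal
rh-inferiorparietal
rh-lateralorbitofrontal
rh-medialorbitofrontal
rh-parsopercularis
rh-parsorbitalis
rh-parstriangularis
rh-precuneus
rh-rostralanteriorcingulate
rh-rostralmiddlefrontal
rh-superiorfrontal
rh-superiorparietal
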