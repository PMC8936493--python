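lh-bankssts
lh-caudalanteriorcingulate
lh-caudalmiddlefrontal
lh-cuneus
lh-entorhinal
lh-fusiform
lh-inferiorparietal
lh-inferiortemporal
lh-isthmuscingulate
lh-lateraloccipital
lh-lateralorbitofrontal
lh-lingual
lh-medialorbitofrontal
lh-middletemporal
lh-parahippocampal
lh-paracentral
lh-parsopercularis
lh-parsorbitalis
lh-parstriangularis
lh-pericalcarine
lh-postcentral
lh-posteriorcingulate
lh-precentral
lh-precuneus
lh-rostralanteriorcingulate
lh-rostralmiddlefrontal
lh-superiorfrontal
lh-superiorparietal
lh-superiortemporal
lh-supramarginal
lh-frontalpole
lh-temporalpole
lh-transversetemporal
lh-insula
rh-bankssts
rh-caudalanteriorcingulate
rh-caudalmiddlefrontal
rh-cuneus
rh-entorhinal
rh-fusiform
rh-inferiorparietal
rh-inferiortemporal
rh-isthmuscingulate
rh-lateraloccipital
rh-lateralorbitofrontal
rh-lingual
rh-medialorbitofrontal
rh-middletemporal
rh-parahippocampal
rh-paracentral
rh-parsopercularis
rh-parsorbitalis
rh-parstriangularis
rh-pericalcarine
rh-postcentral
rh-posteriorcingulate
rh-precentral
rh-precuneus
rh-rostralanteriorcingulate
rh-rostralmiddlefrontal
rh-superiorfrontal
rh-superiorparietal
rh-superiortemporal
rh-supramarginal
rh-frontalpole
rh-temporalpole
rh-transversetemporal
rh-insula
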