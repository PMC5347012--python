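name,kind,hemisphere
lh_bankssts_thickness,thickness,left
lh_caudalanteriorcingulate_thickness,thickness,left
lh_caudalmiddlefrontal_thickness,thickness,left
lh_cuneus_thickness,thickness,left
lh_entorhinal_thickness,thickness,left
lh_fusiform_thickness,thickness,left
lh_inferiorparietal_thickness,thickness,left
lh_inferiortemporal_thickness,thickness,left
lh_isthmuscingulate_thickness,thickness,left
lh_lateraloccipital_thickness,thickness,left
lh_lateralorbitofrontal_thickness,thickness,left
lh_lingual_thickness,thickness,left
lh_medialorbitofrontal_thickness,thickness,left
lh_middletemporal_thickness,thickness,left
lh_parahippocampal_thickness,thickness,left
lh_paracentral_thickness,thickness,left
lh_parsopercularis_thickness,thickness,left
lh_parsorbitalis_thickness,thickness,left
lh_parstriangularis_thickness,thickness,left
lh_pericalcarine_thickness,thickness,left
lh_postcentral_thickness,thickness,left
lh_posteriorcingulate_thickness,thickness,left
lh_precentral_thickness,thickness,left
lh_precuneus_thickness,thickness,left
lh_rostralanteriorcingulate_thickness,thickness,left
lh_rostralmiddlefrontal_thickness,thickness,left
lh_superiorfrontal_thickness,thickness,left
lh_superiorparietal_thickness,thickness,left
lh_superiortemporal_thickness,thickness,left
lh_supramarginal_thickness,thickness,left
lh_temporalpole_thickness,thickness,left
lh_transversetemporal_thickness,thickness,left
lh_frontalpole_thickness,thickness,left
lh_insula_thickness,thickness,left
rh_bankssts_thickness,thickness,right
rh_caudalanteriorcingulate_thickness,thickness,right
rh_caudalmiddlefrontal_thickness,thickness,right
rh_cuneus_thickness,thickness,right
rh_entorhinal_thickness,thickness,right
rh_fusiform_thickness,thickness,right
rh_inferiorparietal_thickness,thickness,right
rh_inferiortemporal_thickness,thickness,right
rh_isthmuscingulate_thickness,thickness,right
rh_lateraloccipital_thickness,thickness,right
rh_lateralorbitofrontal_thickness,thickness,right
rh_lingual_thickness,thickness,right
rh_medialorbitofrontal_thickness,thickness,right
rh_middletemporal_thickness,thickness,right
rh_parahippocampal_thickness,thickness,right
rh_paracentral_thickness,thickness,right
rh_parsopercularis_thickness,thickness,right
rh_parsorbitalis_thickness,thickness,right
rh_parstriangularis_thickness,thickness,right
rh_pericalcarine_thickness,thickness,right
rh_postcentral_thickness,thickness,right
rh_posteriorcingulate_thickness,thickness,right
rh_precentral_thickness,thickness,right
rh_precuneus_thickness,thickness,right
rh_rostralanteriorcingulate_thickness,thickness,right
rh_rostralmiddlefrontal_thickness,thickness,right
rh_superiorfrontal_thickness,thickness,right
rh_superiorparietal_thickness,thickness,right
rh_superiortemporal_thickness,thickness,right
rh_supramarginal_thickness,thickness,right
rh_temporalpole_thickness,thickness,right
rh_transversetemporal_thickness,thickness,right
rh_frontalpole_thickness,thickness,right
rh_insula_thickness,thickness,right
lh_bankssts_volume,volume,left
lh_caudalanteriorcingulate_volume,volume,left
lh_caudalmiddlefrontal_volume,volume,left
lh_cuneus_volume,volume,left
lh_entorhinal_volume,volume,left
lh_fusiform_volume,volume,left
lh_inferiorparietal_volume,volume,left
lh_inferiortemporal_volume,volume,left
lh_isthmuscingulate_volume,volume,left
lh_lateraloccipital_volume,volume,left
lh_lateralorbitofrontal_volume,volume,left
lh_lingual_volume,volume,left
lh_medialorbitofrontal_volume,volume,left
lh_middletemporal_volume,volume,left
lh_parahippocampal_volume,volume,left
lh_paracentral_volume,volume,left
lh_parsopercularis_volume,volume,left
lh_parsorbitalis_volume,volume,left
lh_parstriangularis_volume,volume,left
lh_pericalcarine_volume,volume,left
lh_postcentral_volume,volume,left
lh_posteriorcingulate_volume,volume,left
lh_precentral_volume,volume,left
lh_precuneus_volume,volume,left
lh_rostralanteriorcingulate_volume,volume,left
lh_rostralmiddlefrontal_volume,volume,left
lh_superiorfrontal_volume,volume,left
lh_superiorparietal_volume,volume,left
lh_superiortemporal_volume,volume,left
lh_supramarginal_volume,volume,left
lh_temporalpole_volume,volume,left
lh_transversetemporal_volume,volume,left
lh_frontalpole_volume,volume,left
lh_insula_volume,volume,left
rh_bankssts_volume,volume,right
rh_caudalanteriorcingulate_volume,volume,right
rh_caudalmiddlefrontal_volume,volume,right
rh_cuneus_volume,volume,right
rh_entorhinal_volume,volume,right
rh_fusiform_volume,volume,right
rh_inferiorparietal_volume,volume,right
rh_inferiortemporal_volume,volume,right
rh_isthmuscingulate_volume,volume,right
rh_lateraloccipital_volume,volume,right
rh_lateralorbitofrontal_volume,volume,right
rh_lingual_volume,volume,right
rh_medialorbitofrontal_volume,volume,right
rh_middletemporal_volume,volume,right
rh_parahippocampal_volume,volume,right
rh_paracentral_volume,volume,right
rh_parsopercularis_volume,volume,right
rh_parsorbitalis_volume,volume,right
rh_parstriangularis_volume,volume,right
rh_pericalcarine_volume,volume,right
rh_postcentral_volume,volume,right
rh_posteriorcingulate_volume,volume,right
rh_precentral_volume,volume,right
rh_precuneus_volume,volume,right
rh_rostralanteriorcingulate_volume,volume,right
rh_rostralmiddlefrontal_volume,volume,right
rh_superiorfrontal_volume,volume,right
rh_superiorparietal_volume,volume,right
rh_superiortemporal_volume,volume,right
rh_supramarginal_volume,volume,right
rh_temporalpole_volume,volume,right
rh_transversetemporal_volume,volume,right
rh_frontalpole_volume,volume,right
rh_insula_volume,volume,right
Left-Lateral-Ventricle,volume,left
Right-Lateral-Ventricle,volume,right
Left-Inf-Lat-Vent,volume,left
Right-Inf-Lat-Vent,volume,right
Left-Cerebellum-White-Matter,volume,left
Right-Cerebellum-White-Matter,volume,right
Left-Cerebellum-Cortex,volume,left
Right-Cerebellum-Cortex,volume,right
Left-Thalamus-Proper,volume,left
Right-Thalamus-Proper,volume,right
Left-Caudate,volume,left
Right-Caudate,volume,right
Left-Putamen,volume,left
Right-Putamen,volume,right
Left-Pallidum,volume,left
Right-Pallidum,volume,right
Left-Hippocampus,volume,left
Right-Hippocampus,volume,right
Left-Amygdala,volume,left
Right-Amygdala,volume,right
Left-Accumbens-area,volume,left
Right-Accumbens-area,volume,right
Left-VentralDC,volume,left
Right-VentralDC,volume,right
Left-vessel,volume,left
Right-vessel,volume,right
Left-choroid-plexus,volume,left
Right-choroid-plexus,volume,right
3rd-Ventricle,volume,none
4th-Ventricle,volume,none
5th-Ventricle,volume,none
Brain-Stem,volume,none
CSF,volume,none
Optic-Chiasm,volume,none
CC_Posterior,volume,none
CC_Mid_Posterior,volume,none
CC_Central,volume,none
CC_Mid_Anterior,volume,none
CC_Anterior,volume,none
WM-hypointensities,volume,bilateral
Left-WM-hypointensities,volume,left
Right-WM-hypointensities,volume,right
non-WM-hypointensities,volume,bilateral
Left-non-WM-hypointensities,volume,left
Right-non-WM-hypointensities,volume,right
Left-Cerebral-White-Matter,volume,left
Right-Cerebral-White-Matter,volume,right
Left-Cerebral-Cortex,volume,left
Right-Cerebral-Cortex,volume,right
SubCortGrayVol,volume,bilateral
SupraTentorialVol,volume,bilateral
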