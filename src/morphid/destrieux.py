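"""Feature-name vocabulary for the morphometric schema.

The regional vocabulary is the Destrieux (aparc.a2009s) cortical
parcellation: 74 gyral/sulcal labels per hemisphere, yielding 148
regional measures per modality (thickness, area, volume) in the naming
convention of FreeSurfer's ``aparcstats2table`` (``lh_<region>_<modality>``).

The 66 extra global/subcortical measure names that complete the 510-feature
ALL set are a reconstruction from standard FreeSurfer ``aseg``/global
statistics names (the original study's exact extra-measure list is not
published in full); every extra name that the study's feature-selection
tables print is included verbatim.
"""

from __future__ import annotations

# 74 Destrieux labels per hemisphere (aparc.a2009s).
DESTRIEUX_REGIONS: tuple[str, ...] = (
    "G_and_S_frontomargin",
    "G_and_S_occipital_inf",
    "G_and_S_paracentral",
    "G_and_S_subcentral",
    "G_and_S_transv_frontopol",
    "G_and_S_cingul-Ant",
    "G_and_S_cingul-Mid-Ant",
    "G_and_S_cingul-Mid-Post",
    "G_cingul-Post-dorsal",
    "G_cingul-Post-ventral",
    "G_cuneus",
    "G_front_inf-Opercular",
    "G_front_inf-Orbital",
    "G_front_inf-Triangul",
    "G_front_middle",
    "G_front_sup",
    "G_Ins_lg_and_S_cent_ins",
    "G_insular_short",
    "G_occipital_middle",
    "G_occipital_sup",
    "G_oc-temp_lat-fusifor",
    "G_oc-temp_med-Lingual",
    "G_oc-temp_med-Parahip",
    "G_orbital",
    "G_pariet_inf-Angular",
    "G_pariet_inf-Supramar",
    "G_parietal_sup",
    "G_postcentral",
    "G_precentral",
    "G_precuneus",
    "G_rectus",
    "G_subcallosal",
    "G_temp_sup-G_T_transv",
    "G_temp_sup-Lateral",
    "G_temp_sup-Plan_polar",
    "G_temp_sup-Plan_tempo",
    "G_temporal_inf",
    "G_temporal_middle",
    "Lat_Fis-ant-Horizont",
    "Lat_Fis-ant-Vertical",
    "Lat_Fis-post",
    "Pole_occipital",
    "Pole_temporal",
    "S_calcarine",
    "S_central",
    "S_cingul-Marginalis",
    "S_circular_insula_ant",
    "S_circular_insula_inf",
    "S_circular_insula_sup",
    "S_collat_transv_ant",
    "S_collat_transv_post",
    "S_front_inf",
    "S_front_middle",
    "S_front_sup",
    "S_interm_prim-Jensen",
    "S_intrapariet_and_P_trans",
    "S_oc_middle_and_Lunatus",
    "S_oc_sup_and_transversal",
    "S_occipital_ant",
    "S_oc-temp_lat",
    "S_oc-temp_med_and_Lingual",
    "S_orbital_lateral",
    "S_orbital_med-olfact",
    "S_orbital-H_Shaped",
    "S_parieto_occipital",
    "S_pericallosal",
    "S_postcentral",
    "S_precentral-inf-part",
    "S_precentral-sup-part",
    "S_suborbital",
    "S_subparietal",
    "S_temporal_inf",
    "S_temporal_sup",
    "S_temporal_transverse",
)

assert len(DESTRIEUX_REGIONS) == 74

# The 11 large-brain-region (LBR) composite measures.
LBR_NAMES: tuple[str, ...] = (
    "EstimatedTotalIntraCranialVol",
    "TotalGrayVol",
    "CSF",
    "WhiteSurfArea_area",
    "Cerebellum-Cortex",
    "SubCortGrayVol",
    "CorticalWhiteMatterVol",
    "WM-hypointensities",
    "Cerebellum-White-Matter",
    "MeanThickness_thickness",
    "CC",
)

_BILATERAL_ASEG = (
    "Lateral-Ventricle",
    "Inf-Lat-Vent",
    "Cerebellum-White-Matter",
    "Cerebellum-Cortex",
    "Thalamus-Proper",
    "Caudate",
    "Putamen",
    "Pallidum",
    "Hippocampus",
    "Amygdala",
    "Accumbens-area",
    "VentralDC",
    "vessel",
    "choroid-plexus",
)

_MIDLINE_AND_GLOBAL = (
    "3rd-Ventricle",
    "4th-Ventricle",
    "5th-Ventricle",
    "Brain-Stem",
    "Optic-Chiasm",
    "non-WM-hypointensities",
    "CC_Posterior",
    "CC_Mid_Posterior",
    "CC_Central",
    "CC_Mid_Anterior",
    "CC_Anterior",
    "lhCortexVol",
    "rhCortexVol",
    "CortexVol",
    "lhCorticalWhiteMatterVol",
    "rhCorticalWhiteMatterVol",
    "SupraTentorialVol",
    "SupraTentorialVolNotVent",
    "BrainSegVol",
    "BrainSegVolNotVent",
    "MaskVol",
    "VentricleChoroidVol",
    "lh_WhiteSurfArea_area",
    "rh_WhiteSurfArea_area",
    "lh_MeanThickness_thickness",
    "rh_MeanThickness_thickness",
    "BrainSegVol-to-eTIV",
)

# 66 extras: 11 LBR composites + bilateral aseg structures + midline/global.
EXTRA_NAMES: tuple[str, ...] = (
    LBR_NAMES
    + tuple(f"{side}-{s}" for s in _BILATERAL_ASEG for side in ("Left", "Right"))
    + _MIDLINE_AND_GLOBAL
)

assert len(EXTRA_NAMES) == len(set(EXTRA_NAMES))


def regional_names(modality: str) -> list[str]:
    """All 148 regional names for one modality, left hemisphere first."""
    return [
        f"{hemi}_{region}_{modality}"
        for hemi in ("lh", "rh")
        for region in DESTRIEUX_REGIONS
    ]
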