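"""Cortical parcellation labels.

The analysis attributes source activity to 148 cortical parcels: the 74
gyral/sulcal structures of the standard Destrieux-style nomenclature, one
per hemisphere (``-lh`` / ``-rh``).  Only the label structure matters to the
pipeline -- parcel geometry in the synthetic head model is schematic -- but
the names are kept so that reduced-model reports read like a cortical map.
"""

from __future__ import annotations

# 74 base structures of the Destrieux (a2009s) gyral/sulcal nomenclature.
_DESTRIEUX_BASE = [
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
]

#: Fixed ordering of the 148 parcel labels used everywhere downstream
#: (feature columns, parcel axis of area-current arrays, tie-breaks).
PARCEL_LABELS: list[str] = [
    f"{base}-{hemi}" for base in _DESTRIEUX_BASE for hemi in ("lh", "rh")
]

#: The 28 parcels that the decoder's reduced model centres on by default --
#: subparietal sulcus, insular structures, anterior/middle cingulate, orbital
#: and opercular frontal cortex and companions.  These double as the default
#: target areas where the synthetic generator injects condition effects, so
#: that effect-recovery checks have a named ground truth.
CREDIBILITY_LOOP_AREAS: list[str] = [
    "S_subparietal-lh",
    "S_subparietal-rh",
    "G_Ins_lg_and_S_cent_ins-rh",
    "G_and_S_cingul-Mid-Ant-lh",
    "S_circular_insula_sup-rh",
    "G_insular_short-lh",
    "S_circular_insula_sup-lh",
    "S_postcentral-rh",
    "S_orbital_med-olfact-lh",
    "Lat_Fis-post-rh",
    "G_rectus-lh",
    "G_and_S_cingul-Mid-Post-lh",
    "S_precentral-sup-part-rh",
    "G_orbital-lh",
    "S_front_sup-lh",
    "G_temp_sup-G_T_transv-rh",
    "S_orbital-H_Shaped-lh",
    "S_temporal_sup-lh",
    "S_intrapariet_and_P_trans-lh",
    "G_front_sup-lh",
    "G_and_S_cingul-Ant-rh",
    "G_front_inf-Opercular-rh",
    "S_suborbital-lh",
    "G_rectus-rh",
    "G_front_inf-Opercular-lh",
    "G_orbital-rh",
    "G_temp_sup-G_T_transv-lh",
    "G_precentral-rh",
]

N_PARCELS = len(PARCEL_LABELS)

assert N_PARCELS == 148
assert len(set(PARCEL_LABELS)) == 148
assert set(CREDIBILITY_LOOP_AREAS) <= set(PARCEL_LABELS)


def parcel_index(label: str) -> int:
    """Position of ``label`` in the fixed parcel ordering."""
    try:
        return PARCEL_LABELS.index(label)
    except ValueError:
        raise KeyError(f"unknown parcel label: {label!r}") from None
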