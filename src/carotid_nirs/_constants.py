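"""Shared vocabulary: patch locations, artery pairs, feature names, conventions.

Units are carried in column-name suffixes throughout the package:
``_uM`` (micromolar), ``_pct`` (percent), ``_s`` (seconds), ``_mm``, ``_nm``,
``_db`` (decibels).
"""

LOCATIONS = ("left_radial", "right_radial", "left_carotid", "right_carotid")

#: Artery pairs entering equivalence testing: each carotid against the
#: ipsilateral radial reference, plus left-vs-right within artery type.
ARTERY_PAIRS = (
    ("left_radial", "left_carotid"),
    ("right_radial", "right_carotid"),
    ("left_radial", "right_radial"),
    ("left_carotid", "right_carotid"),
)

#: The six parameters of interest, one column per feature.
FEATURE_COLUMNS = (
    "bh_max_pct_change_hbt_pct",
    "bh_max_pct_change_sto2_pct",
    "db_mean_osc_time_hbt_s",
    "db_mean_osc_time_sto2_s",
    "db_mean_pkpk_hbt_uM",
    "db_mean_pkpk_sto2_pct",
)

#: Oscillation time = mean interval between adjacent *alternating* extrema
#: (peak to the next trough), i.e. a half-period for a pure sinusoid.  The
#: waveform generator and the feature extractor must both use this convention;
#: both import this constant so agreement is structural, not accidental.
OSC_TIME_CONVENTION = "adjacent_alternating_extrema"

SKIN_TONES = ("fair", "olive", "dark")
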