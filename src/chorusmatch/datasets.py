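"""Bundled reference tables from a published multi-species frog
recogniser evaluation (eight species, Murray–Darling Basin river red
gum forest; SongMeter recorders at 44 kHz).

Three small tables ship with the package for regression-testing the
metric layer against real-world numbers:

- per-species evaluation-file counts,
- per-template confusion counts with the printed 3-dp metrics and the
  flag marking templates excluded from the final recognisers,
- false-positive source percentages per species.

The underlying audio is proprietary and is not (and cannot be)
included; these tables pin the arithmetic, not the matching.
"""

from __future__ import annotations

import io

import pandas as pd

from .evaluation import ConfusionCounts

__all__ = [
    "load_evaluation_file_counts",
    "load_recogniser_performance",
    "load_fp_source_percentages",
    "performance_row_counts",
]

_EVALUATION_FILE_COUNTS_CSV = """\
species,n_evaluation_files
Crinia signifera,300
Limnodynastes tasmaniensis,146
Limnodynastes fletcherii,78
Limnodynastes dumerilii,74
Litoria peronii,118
Crinia parinsignifera,298
Neobatrachus sudelli,62
Litoria raniformis,24
"""

_RECOGNISER_PERFORMANCE_CSV = """\
species,template_name,count_fp,count_tp,call_precision,pa_fp,pa_tp,pa_fn,pa_tn,survey_precision,survey_recall,roc,excluded
Crinia signifera,-43_129_SM4S,1048,7963,0.884,28,116,34,122,0.806,0.773,0.793,0
Crinia signifera,-46_130_SM4S,4432,18488,0.807,41,127,23,109,0.756,0.847,0.787,1
Crinia signifera,-47_183_SM4H,2211,18609,0.894,40,120,30,110,0.750,0.800,0.767,0
Limnodynastes tasmaniensis,512 5khz_-27_95_SM3-E+0,10509,4245,0.288,37,46,27,36,0.554,0.630,0.562,0
Limnodynastes tasmaniensis,512 5khz_-32_45_SM4G,18671,9747,0.343,46,60,13,27,0.566,0.822,0.596,1
Limnodynastes tasmaniensis,512 5khz_-32_90_SM3-E+0,1807,1134,0.386,25,37,36,48,0.597,0.507,0.582,0
Limnodynastes fletcherii,-23_95_SM3-E,52,9438,0.995,7,36,3,32,0.837,0.923,0.872,0
Limnodynastes fletcherii,-25_29_SM4G,2,1041,0.998,1,27,12,38,0.964,0.692,0.833,0
Limnodynastes fletcherii,-31_54_SM4G,381,6531,0.945,6,37,2,33,0.860,0.949,0.897,0
Limnodynastes fletcherii,-34_3_SM3-E,903,1866,0.674,14,38,1,25,0.731,0.974,0.808,1
Limnodynastes dumerilii,-18_104_SM3-E,47,3253,0.986,11,35,2,26,0.761,0.946,0.824,1
Limnodynastes dumerilii,-18_106_SM3-E,7,1964,0.996,4,32,5,33,0.889,0.865,0.878,0
Limnodynastes dumerilii,-28_97_20181022 (SM4G),3,4043,0.999,2,33,4,35,0.943,0.892,0.919,0
Limnodynastes dumerilii,-35_30_SM4G,19,3452,0.995,5,36,1,32,0.878,0.973,0.919,0
Litoria peronii,-30_256_60_SM3-E,31,1874,0.984,9,45,14,50,0.833,0.763,0.805,0
Litoria peronii,-31_512_65_SM3-E,9,806,0.989,5,46,13,54,0.902,0.780,0.847,0
Litoria peronii,-38_256_75_SM3-E,2,678,0.997,1,42,17,58,0.977,0.712,0.847,0
Crinia parinsignifera,-30_37_SM4S,1273,6201,0.830,33,100,49,116,0.752,0.671,0.725,0
Crinia parinsignifera,-33_38_SM4S,1520,4563,0.750,26,91,58,123,0.778,0.611,0.718,0
Crinia parinsignifera,-41_47_SM3-E0+1,6707,10575,0.612,58,109,40,91,0.653,0.732,0.671,1
Neobatrachus sudelli,-23_512_94_SM4M,105,3032,0.967,1,31,0,30,0.969,1.000,0.984,0
Neobatrachus sudelli,-39_512_100_SM4M,36,2645,0.987,1,31,0,30,0.969,1.000,0.984,0
Neobatrachus sudelli,-52_512_1_SM4M,3,2097,0.999,1,31,0,30,0.969,1.000,0.984,0
Litoria raniformis,-36_512_24_SM4R,0,28,1.000,0,10,2,12,1.000,0.833,0.917,0
Litoria raniformis,-42_512_85_SM4R,8,962,0.992,2,12,0,10,0.857,1.000,0.917,0
Litoria raniformis,-44_512_99_SM4R,0,100,1.000,0,10,2,12,1.000,0.833,0.917,0
"""

_FP_SOURCE_PERCENTAGES_CSV = """\
category,Crinia signifera,Limnodynastes tasmaniensis,Limnodynastes fletcherii,Limnodynastes dumerilii,Litoria peronii,Crinia parinsignifera,Neobatrachus sudelli,Litoria raniformis
anthropogenic,0.1,9.9,3.3,33.3,0,0,0,13.2
water_sounds,0.2,0.1,0,4.8,7.0,0,0,0
birds,10.5,0,9.1,52.4,72.1,0,8.2,30.9
insects,46.5,0,48.1,0,0,66.1,30.8,0
other_geophony,0,0.1,0,0,2.3,33.9,0,1.5
other_animals,0,0,0.4,0,0,0,8.9,0
other_frogs,41.7,50.6,35.3,0,4.6,0,52.1,54.1
weather,0.8,39.3,3.7,9.5,14.0,0,0,0.2
"""


def load_evaluation_file_counts() -> pd.DataFrame:
    """Number of annotated evaluation files per species."""
    return pd.read_csv(io.StringIO(_EVALUATION_FILE_COUNTS_CSV))


def load_recogniser_performance() -> pd.DataFrame:
    """Per-template confusion counts and printed 3-dp metrics (26 templates)."""
    return pd.read_csv(io.StringIO(_RECOGNISER_PERFORMANCE_CSV))


def load_fp_source_percentages() -> pd.DataFrame:
    """False-positive source percentages per species (categories × species)."""
    return pd.read_csv(io.StringIO(_FP_SOURCE_PERCENTAGES_CSV), index_col="category")


def performance_row_counts(row: pd.Series) -> ConfusionCounts:
    """Build :class:`ConfusionCounts` from one performance-table row."""
    n_files = int(row.pa_tp + row.pa_fp + row.pa_fn + row.pa_tn)
    return ConfusionCounts(
        count_tp=int(row.count_tp), count_fp=int(row.count_fp),
        pa_tp=int(row.pa_tp), pa_fp=int(row.pa_fp),
        pa_fn=int(row.pa_fn), pa_tn=int(row.pa_tn),
        n_files=n_files,
    )
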