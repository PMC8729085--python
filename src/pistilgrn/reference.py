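"""Published summary numbers from the papaya pistil transcriptome study.

These are bookkeeping inputs — per-contrast shared-DEG counts, per-network
hub counts, the RT-qPCR validation tally, and the curated table of
sex-specific hub transcription factors — used for consistency checks of the
pipeline's accounting rules (per-contrast counting, top-decile hub pooling,
expression-rule parsing) against the study's printed totals.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: shared DEGs (intersection of both DE methods) per stage contrast
SHARED_DEG_COUNTS = {
    "FS1_vs_MS1": 1397,
    "FS2_vs_MS2": 1403,
    "FS3_vs_MS3": 1386,
    "FS4_vs_MS4": 2872,
}
#: printed total of shared DEGs across contrasts
SHARED_DEG_TOTAL = 7058
#: DEG totals of the two individual methods
METHOD_DEG_TOTALS = {"A": 7165, "B": 8074}

#: candidate hub genes (top 10% by degree) per stage network
HUB_COUNTS = {"FS1": 70, "FS2-3": 122, "FS4": 587, "MS1": 11, "MS2-3": 248, "MS4": 259}
#: printed pooled hub total across the six networks
HUB_TOTAL = 1297

#: RT-qPCR validation of the SS preferential-expression calls
QPCR_TESTED = 24
QPCR_CONSISTENT = 19
QPCR_CONSISTENT_PCT = 79.2

#: sex-specific hub TF counts as stated in the running text
FEMALE_SPECIFIC_TF_COUNT = 18
MALE_SPECIFIC_TF_COUNT_TEXT = 7  # the printed table transcribes only 6 male rows


def load_hub_tf_table() -> pd.DataFrame:
    """Curated table of sex-specific hub TFs (expression-rule flags per sex)."""
    with resources.files("pistilgrn.data").joinpath("hub_tf_table.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def count_sex_specific_rows(table: pd.DataFrame) -> tuple[int, int]:
    """(female-specific, male-specific) row counts under the expression rule."""
    female = int(((table["female"] == "EXP") & (table["male"] == "NO")).sum())
    male = int(((table["male"] == "EXP") & (table["female"] == "NO")).sum())
    return female, male


def qpcr_concordance_pct(consistent: int = QPCR_CONSISTENT, tested: int = QPCR_TESTED) -> float:
    """Validated/tested tally as the percentage the study reports (1 dp)."""
    if tested <= 0:
        raise ValueError("tested must be positive")
    return round(100.0 * consistent / tested, 1)
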