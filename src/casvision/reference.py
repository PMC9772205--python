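"""Bundled reference tables from a published clinical evaluation.

Two pooled predicted-vs-reference CAS cross-tabulations (entire-cohort
and rater-consistent-subset test protocols, each pooled over 30
repeated splits) and the cohort's headline counts.  They serve as
worked-example inputs for the agreement and prevalence statistics; the
package never fits models to them.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .evaluation import CasConfusion

_DATA = files("casvision") / "data"


def reference_confusion(protocol: str) -> CasConfusion:
    """Pooled 8x8 CAS confusion for ``"entire"`` or ``"consistent"``."""
    if protocol not in ("entire", "consistent"):
        raise ValueError(f"unknown protocol {protocol!r}")
    with (_DATA / f"cas_confusion_{protocol}.csv").open() as fh:
        return CasConfusion.from_csv(fh)


def cohort_counts() -> pd.DataFrame:
    """Headline cohort counts (sign prevalences, pains, activity), indexed by item."""
    with (_DATA / "clinical_cohort_counts.csv").open() as fh:
        return pd.read_csv(fh, index_col="item")


def prevalence_pct(item: str) -> float:
    """Percent prevalence of a counted item, e.g. ``"active_tao"``."""
    row = cohort_counts().loc[item]
    return 100.0 * float(row["count"]) / float(row["denominator"])
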