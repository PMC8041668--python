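"""Whole-body tumor burden biomarkers.

Three per-patient sums over segmented lesions:

* PSMA-TV  = Σ TV                 (total tumor volume, ml)
* PSMA-TLU = Σ TV · SUVmean       (total lesion uptake, ml·SUV)
* PSMA-TLQ = Σ TV / SUVmean       (total lesion quotient, ml/SUV)

TLQ combines tumor volume (negative prognosticator) and uptake (positive
prognosticator) without the antagonism that affects TLU.  Metrics are stored
on the raw scale; the log2 transform happens only in the statistical stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from psmaburden.segmentation import Lesion, LiverReference

__all__ = ["PatientBurden", "MetricDomainError", "compute_burden", "burden_table", "lesion_table"]


class MetricDomainError(ValueError):
    """A lesion with SUVmean <= 0 makes PSMA-TLQ undefined."""


@dataclass(frozen=True)
class PatientBurden:
    """Per-patient lesion list and whole-body burden metrics."""

    patient_id: str
    lesions: tuple[Lesion, ...]
    psma_tv: float
    psma_tlu: float
    psma_tlq: float
    liver: LiverReference | None = field(default=None, compare=False)

    @property
    def lesion_count(self) -> int:
        return len(self.lesions)


def compute_burden(patient_id: str, lesions, liver: LiverReference | None = None) -> PatientBurden:
    """Sum per-lesion contributions into whole-body PSMA-TV/TLU/TLQ.

    Every lesion must have ``suv_mean > 0`` (the TLQ term divides by it);
    an empty lesion list yields all metrics 0.
    """
    lesions = tuple(lesions)
    for les in lesions:
        if les.suv_mean <= 0:
            raise MetricDomainError(
                f"lesion with SUVmean {les.suv_mean} in patient {patient_id!r}: PSMA-TLQ undefined"
            )
    return PatientBurden(
        patient_id=str(patient_id),
        lesions=lesions,
        psma_tv=float(sum(les.volume_ml for les in lesions)),
        psma_tlu=float(sum(les.tlu_contribution for les in lesions)),
        psma_tlq=float(sum(les.tlq_contribution for les in lesions)),
        liver=liver,
    )


def burden_table(burdens) -> pd.DataFrame:
    """One row per patient: lesion_count, psma_tv_ml, psma_tlu, psma_tlq."""
    burdens = list(burdens)
    ids = [b.patient_id for b in burdens]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate patient_id(s): {sorted(dupes)}")
    return pd.DataFrame(
        {
            "patient_id": ids,
            "lesion_count": [b.lesion_count for b in burdens],
            "psma_tv_ml": [b.psma_tv for b in burdens],
            "psma_tlu": [b.psma_tlu for b in burdens],
            "psma_tlq": [b.psma_tlq for b in burdens],
        }
    )


def lesion_table(burdens) -> pd.DataFrame:
    """One row per lesion across patients (per-lesion CSV export schema)."""
    rows = []
    for b in burdens:
        for k, les in enumerate(b.lesions, start=1):
            rows.append(
                {
                    "patient_id": b.patient_id,
                    "lesion_id": k,
                    "provenance": les.provenance,
                    "volume_ml": les.volume_ml,
                    "suv_max": les.suv_max,
                    "suv_mean": les.suv_mean,
                    "suv_peak": les.suv_peak,
                    "tlu_contribution": les.tlu_contribution,
                    "tlq_contribution": les.tlq_contribution,
                }
            )
    columns = [
        "patient_id", "lesion_id", "provenance", "volume_ml", "suv_max",
        "suv_mean", "suv_peak", "tlu_contribution", "tlq_contribution",
    ]
    return pd.DataFrame(rows, columns=columns)
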