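"""Bundled field-verification inputs.

Two small tables from the Ku-band rice survey back the verification
arithmetic: per-parcel yield components measured at harvest (effective ear
density, grains per ear, thousand-grain weight, total output) and the
model-estimated yields for the mature parcel (B) and the grouting-stage
composite parcel (C+D+E).
"""

from importlib import resources
from typing import List

import pandas as pd

from .yield_pipeline import FieldTruthRecord

__all__ = [
    "field_survey_yield",
    "yield_model_estimates",
    "field_truth_records",
    "read_field_truth_csv",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("ricewcm.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def field_survey_yield() -> pd.DataFrame:
    """Per-parcel measured yield components (harvest survey)."""
    return _read("field_survey_yield.csv")


def yield_model_estimates() -> pd.DataFrame:
    """Model-estimated wet and dried yields per parcel and model, kg/mu."""
    return _read("yield_model_estimates.csv")


def read_field_truth_csv(path) -> List[FieldTruthRecord]:
    """Read any survey CSV with the bundled table's columns into records."""
    return _records(pd.read_csv(path))


def field_truth_records() -> List[FieldTruthRecord]:
    """The bundled survey table as typed records."""
    return _records(field_survey_yield())


def _records(df: pd.DataFrame) -> List[FieldTruthRecord]:
    return [
        FieldTruthRecord(
            parcel_id=str(r.parcel_id),
            effective_ears=float(r.effective_ears_1e4_hm2),
            grains_per_ear_total=float(r.grains_per_ear_total),
            grains_per_ear_filled=float(r.grains_per_ear_filled),
            thousand_grain_weight=float(r.thousand_grain_weight_g),
            total_output=float(r.total_output_kg_hm2),
            yield_per_mu=float(r.yield_per_mu_kg),
        )
        for r in df.itertuples()
    ]
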