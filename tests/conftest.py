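import numpy as np
import pandas as pd
import pytest

from nukaflow.tables_io import (
    FeatureTable,
    Lineage,
    SampleMetadata,
    SampleMetadataSet,
    TaxonomyMap,
)
from nukaflow.synthetic_data import SimulationParams, generate_study


@pytest.fixture
def small_table() -> FeatureTable:
    df = pd.DataFrame(
        {"S1": [10, 5, 0], "S2": [0, 7, 3]},
        index=pd.Index(["ASV1", "ASV2", "ASV3"], name="feature_id"),
        dtype=np.int64,
    )
    return FeatureTable(df)


@pytest.fixture
def small_tax() -> TaxonomyMap:
    return TaxonomyMap(
        {
            "ASV1": Lineage(("d__Bacteria", "p__Firmicutes", "c__Bacilli",
                             "o__Lactobacillales", "f__Lactobacillaceae",
                             "g__Loigolactobacillus", "")),
            "ASV2": Lineage(("d__Bacteria", "p__Proteobacteria", "c__Gamma",
                             "o__Enterobacterales", "f__Erwiniaceae",
                             "g__Pantoea", "")),
            "ASV3": Lineage(("Unassigned",)),
        }
    )


@pytest.fixture
def study_layout_meta() -> SampleMetadataSet:
    """The study's sampling schedule: bed days {0,3,6,9,12,14}, skin
    timepoints {0, 0', 3, ..., 29}, for three subjects."""
    records = []
    for subject in ("1", "2", "3"):
        for day in (0, 3, 6, 9, 12, 14):
            records.append(
                SampleMetadata(
                    sample_id=f"sub{subject}_nuka_d{day:02d}",
                    subject=subject,
                    substrate="nukadoko",
                    day=day,
                    timepoint_label=str(day),
                    phase="contact",
                )
            )
        for label in ("0", "0'", "3", "6", "9", "12", "14",
                      "15", "18", "21", "24", "27", "29"):
            day = int(label.rstrip("'"))
            records.append(
                SampleMetadata(
                    sample_id="sub{}_skin_{}".format(subject, label.replace("'", "p")),
                    subject=subject,
                    substrate="skin",
                    day=day,
                    timepoint_label=label,
                    phase="contact" if day <= 14 else "no_contact",
                )
            )
    return SampleMetadataSet(records)


@pytest.fixture(scope="session")
def default_study():
    """One study-shaped simulation under default conditions."""
    return generate_study(SimulationParams(master_seed=7))
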