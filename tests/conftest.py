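import numpy as np
import pandas as pd
import pytest

from cdksig import Contrast, ExpressionMatrix, SampleAnnotation


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples with easy-to-track values."""
    return ExpressionMatrix(
        gene_ids=("g1", "g2", "g3"),
        sample_ids=("t1", "t2", "c1", "c2"),
        values=np.array(
            [
                [4.0, 4.0, 5.0, 5.0],
                [2.0, 3.0, 2.0, 3.0],
                [7.0, 7.5, 6.0, 6.5],
            ]
        ),
    )


@pytest.fixture
def simple_contrast() -> Contrast:
    return Contrast(
        name="demo",
        treated_sample_ids=("t1", "t2"),
        control_sample_ids=("c1", "c2"),
    )


@pytest.fixture
def annotation_frame() -> pd.DataFrame:
    rows = []
    for model, rb in [("MCF7", "proficient"), ("MB468", "deficient")]:
        for agent, dose in [("vehicle", 0.0), ("LY", 250.0)]:
            for rep in (1, 2, 3):
                rows.append(
                    {
                        "sample_id": f"{model}_{agent}_{rep}",
                        "model": model,
                        "rb_status": rb,
                        "agent": agent,
                        "dose_nM": dose,
                        "context": "cell_line",
                        "replicate": rep,
                    }
                )
    return pd.DataFrame(rows)


@pytest.fixture
def annotation(annotation_frame) -> SampleAnnotation:
    return SampleAnnotation(annotation_frame)
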