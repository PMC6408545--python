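import numpy as np
import pandas as pd
import pytest

from comonet import ExpressionMatrix, SampleGroups, CtTable


@pytest.fixture
def tiny_expression() -> ExpressionMatrix:
    """3 probes × 4 samples, hand-written values."""
    df = pd.DataFrame(
        [[4.0, 2.0, 3.0, 3.0], [5.0, 7.0, 6.0, 6.0], [1.0, 1.0, 1.0, 1.0]],
        index=["P1", "P2", "P3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(df)


@pytest.fixture
def two_group_labels() -> SampleGroups:
    return SampleGroups({"s1": "case", "s2": "case", "s3": "ctrl", "s4": "ctrl"})


@pytest.fixture
def toy_ct_table() -> CtTable:
    """Three stable references (20/22/21) and one target shifted by 1 cycle."""
    df = pd.DataFrame(
        {
            "a_ctrl": [20.0, 22.0, 21.0, 25.0],
            "a_trt": [20.0, 22.0, 21.0, 24.0],
        },
        index=["REF1", "REF2", "REF3", "TARGET"],
    )
    return CtTable(df, {"a_ctrl": "control", "a_trt": "treated"}, ["REF1", "REF2", "REF3"])


def make_signature(sample_id, ranking, n1, n2):
    from comonet import SubjectSignature

    ranking = tuple(ranking)
    return SubjectSignature(
        sample_id=sample_id,
        up=ranking[:n1],
        down=ranking[len(ranking) - n2:],
        ranking=ranking,
    )
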