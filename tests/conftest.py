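import pytest

from ppibias.data_model import Interaction, InteractionDataset
from ppibias.metrics import PredictionRecord, PredictionSet


@pytest.fixture
def toy6_dataset() -> InteractionDataset:
    """Six interactions over proteins A..D with hand-checkable stats.

    A-B:+, A-C:-, A-D:-, B-C:+, B-D:+, C-D:-
    """
    return InteractionDataset.from_records(
        [
            Interaction("A", "B", 1),
            Interaction("A", "C", 0),
            Interaction("A", "D", 0),
            Interaction("B", "C", 1),
            Interaction("B", "D", 1),
            Interaction("C", "D", 0),
        ]
    )


@pytest.fixture
def toy6_predictions(toy6_dataset) -> PredictionSet:
    """The worked pp_MCC example: (true, pred) pairs
    A-B(+,+), A-C(-,+), A-D(-,-), B-C(+,-), B-D(+,+), C-D(-,-).

    Hand enumeration: A(TP=1,TN=1,FP=1,FN=0) -> MCC 0.5; B has no actual
    negatives -> skipped; C(TN=1,FP=1,FN=1) -> MCC -0.5; D(TP=1,TN=2) ->
    MCC 1.0; weights 3 each -> pp_MCC = (0.5 - 0.5 + 1.0) / 3 = 1/3.
    """
    preds = [1, 1, 0, 0, 1, 0]
    return PredictionSet(
        [
            PredictionRecord(it, p, fold_id=0)
            for it, p in zip(toy6_dataset.interactions, preds)
        ]
    )
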