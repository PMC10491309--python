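import numpy as np
import pytest

from riboclast.annotation import TranscriptModel, TranscriptomeSet, UORFAnnotation


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def simple_model():
    """The canonical 300-nt transcript: 5'UTR [0,100), CDS [100,250),
    3'UTR [250,300)."""
    return TranscriptModel("tx1", "g1", 300, 100, 250)


@pytest.fixture
def uorf_model():
    """A transcript with an ATF4-style uORF overlapping the CDS start."""
    return TranscriptModel(
        "tx2", "g2", 300, 100, 250,
        uorfs=[UORFAnnotation(80, 131, "AUG")],
    )


def make_transcriptome(models, sequences=None):
    return TranscriptomeSet(models, sequences=sequences)


@pytest.fixture
def tiny_transcriptome(simple_model, uorf_model):
    return make_transcriptome([simple_model, uorf_model])


def random_sequence(rng, length):
    return "".join(rng.choice(list("ACGU"), size=length))
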