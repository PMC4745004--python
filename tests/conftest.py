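import hypothesis
import pytest

import mirepress as mr

hypothesis.settings.register_profile(
    "repro", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_dataset() -> mr.SyntheticDataset:
    """The default synthetic study design (4 control + 4 tumor, 4 planted pathways)."""
    return mr.simulate_dataset(mr.SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def default_result(default_dataset) -> mr.PipelineResult:
    ds = default_dataset
    return mr.analyze(
        ds.profiles,
        ds.interactions,
        ds.pathways,
        control_ids=ds.control_ids,
        test_ids=ds.test_ids,
    )


def make_tpm(sample_id: str, tpm: dict) -> mr.NormalizedProfile:
    """Pad an abundance dict with a target-less filler miRNA so TPM sums to 1e6.

    Lets tests state repression examples on small round abundances while
    honoring the normalized-profile invariant; the filler has no targets and
    contributes nothing downstream.
    """
    total = sum(tpm.values())
    filler = 1_000_000.0 - total
    assert filler >= 0
    padded = dict(tpm)
    if filler > 0:
        padded["__filler__"] = filler
    return mr.NormalizedProfile(sample_id, padded)
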