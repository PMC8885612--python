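import pytest

from ccperiods import generate_case, preset, write_case, write_segmentation


@pytest.fixture(scope="session")
def clean_case():
    """The clean preset rendered once: (CaseRecord, GroundTruth)."""
    return generate_case(preset("clean"))


@pytest.fixture(scope="session")
def clean_case_dir(tmp_path_factory, clean_case):
    """The clean preset written out as a full case directory."""
    record, truth = clean_case
    case_dir = tmp_path_factory.mktemp("case") / "Case_clean"
    write_case(record, case_dir)
    write_segmentation(truth.periods, case_dir / "ground_truth.csv")
    return case_dir
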