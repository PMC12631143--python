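import pandas as pd
import pytest
from hypothesis import settings

from ldmtx import pbpk, synthetic_data
from ldmtx.rcs_model import REFERENCE_MODEL

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params() -> pbpk.PBPKParameters:
    return pbpk.default_parameters()


@pytest.fixture(scope="session")
def reference_model():
    return REFERENCE_MODEL


@pytest.fixture(scope="session")
def planted_corpus_dir(tmp_path_factory):
    """Synthetic report corpus with one planted drug x PT signal."""
    out = tmp_path_factory.mktemp("faers")
    plan = synthetic_data.default_signal_plan(seed=1, n_cases=6000)
    synthetic_data.generate_faers_tables(plan, out)
    return out


def make_case(primary_id, case_id, drugs, reactions, indications=("Renal failure",),
              sex="F", age=60.0, country="US", reporter="physician",
              year=2020, dose=7.5):
    return {
        "primary_id": primary_id, "case_id": case_id, "sex": sex,
        "age_years": age, "country": country, "reporter": reporter,
        "report_year": year, "mtx_dose_mg": dose,
        "drugs": frozenset(drugs),
        "indication_pts": frozenset(indications),
        "reaction_pts": frozenset(reactions),
    }


@pytest.fixture
def hand_cases() -> pd.DataFrame:
    """Four hand-built cases for hand-counted contingency checks.

    methotrexate cases: #1 {Nausea, Rash}, #2 {Nausea};
    other-drug cases:   #3 {Nausea, Fatigue}, #4 {Rash}.
    """
    return pd.DataFrame([
        make_case(11, 1, {"methotrexate"}, {"Nausea", "Rash"}),
        make_case(21, 2, {"methotrexate", "folic acid"}, {"Nausea"}),
        make_case(31, 3, {"prednisone"}, {"Nausea", "Fatigue"}),
        make_case(41, 4, {"ibuprofen"}, {"Rash"}),
    ])
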