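import pytest

from aifex.core import Dataset, GoldAnnotation, Report
from aifex.prompting import load_template
from aifex.synth import generate_dataset, internal_profile


@pytest.fixture(scope="session")
def cot_json_template():
    return load_template("cot-json")


@pytest.fixture(scope="session")
def small_dataset():
    """Hand-built 3-report dataset: one positive (two AIF sentences,
    one being an Interpretation restatement), one positive (single AIF),
    one negative."""
    r1_text = (
        "Clinical details: Staging of known left lung carcinoma.\n"
        "Findings:\n"
        "1. There is an intensely FDG-avid 4.1 cm mass in the left upper lobe.\n"
        "2. Severe emphysema is noted in the upper lobes.\n"
        "3. The prostate is enlarged.\n"
        "Interpretation:\n"
        "Severe emphysema is noted in the upper lobes, as above."
    )
    r2_text = (
        "Findings:\n"
        "There is a 4.8 cm infrarenal abdominal aortic aneurysm.\n"
        "Mild emphysema is noted in both lungs.\n"
        "Interpretation:\n"
        "Appearances are in keeping with the known lung primary."
    )
    r3_text = (
        "Findings:\n"
        "Moderate emphysema is present in the lower lobes.\n"
        "No suspicious FDG-avid bone lesions are identified.\n"
        "Interpretation:\n"
        "No further significant incidental abnormality is identified."
    )
    reports = [
        Report("r1", r1_text),
        Report("r2", r2_text),
        Report("r3", r3_text),
    ]
    annotations = {
        "r1": GoldAnnotation(
            "r1",
            (
                "Severe emphysema is noted in the upper lobes.",
                "Severe emphysema is noted in the upper lobes, as above.",
            ),
        ),
        "r2": GoldAnnotation(
            "r2", ("There is a 4.8 cm infrarenal abdominal aortic aneurysm.",)
        ),
        "r3": GoldAnnotation("r3", ()),
    }
    ds = Dataset("fixture", reports, annotations)
    ds.validate_grounding()
    return ds


@pytest.fixture(scope="session")
def internal_dataset():
    """A 100-report synthetic internal-profile corpus (fixed seed)."""
    return generate_dataset(internal_profile(100, seed=11))
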