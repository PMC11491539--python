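import numpy as np
import pytest

from ecgstemi import CalibrationSpec, CaseSpec, LeadID, NoiseParams, build_layout


@pytest.fixture(scope="session")
def layout():
    return build_layout()


@pytest.fixture(scope="session")
def calib():
    return CalibrationSpec()


def make_case(
    per_lead_mm: dict[LeadID, float],
    seed: int = 0,
    label: str | None = None,
    territories: frozenset[str] = frozenset(),
    noise: NoiseParams | None = None,
    heart_rate: float = 75.0,
) -> CaseSpec:
    """Case with on-paper elevations given in mm (converted at gain 10)."""
    if label is None:
        label = "STEMI" if territories else "NSTEMI"
    return CaseSpec(
        label=label,
        territories=territories,
        per_lead_st_mV={lead: mm / 10.0 for lead, mm in per_lead_mm.items()},
        seed=seed,
        heart_rate_bpm=heart_rate,
        noise=noise or NoiseParams.none(),
    )


@pytest.fixture(scope="session")
def inferior_case_rendered(layout, calib):
    """Clean inferior STEMI at 2 mm in II and III, with its ground truth."""
    from ecgstemi import render_case

    spec = make_case(
        {LeadID.II: 2.0, LeadID.III: 2.0},
        seed=7,
        territories=frozenset({"inferior"}),
    )
    image, boxes = render_case(spec, layout, calib)
    return spec, image, boxes
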