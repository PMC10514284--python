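import datetime as dt

import pytest

from targetrank import CohortSpec, EvidenceDocument, generate_cohort

TODAY = dt.date(2023, 1, 1)


@pytest.fixture(scope="session")
def small_spec() -> CohortSpec:
    return CohortSpec(
        n_targets=60,
        n_planted_top=3,
        seed=11,
        n_deg_up=12,
        n_deg_down=4,
        n_variants=150,
    )


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory, small_spec):
    """One small generated cohort shared across the session: (dir, truth)."""
    out = tmp_path_factory.mktemp("cohort")
    truth = generate_cohort(small_spec, out)
    return out, truth


def make_doc(
    target="IL13",
    asset_class="publication",
    date=TODAY,
    position="title",
    impact_factor=None,
    citations=None,
    phase=None,
    status=None,
    doc_id="d1",
) -> EvidenceDocument:
    return EvidenceDocument(
        doc_id=doc_id,
        asset_class=asset_class,
        target=target,
        date=date,
        position=position,
        impact_factor=impact_factor,
        citations=citations,
        phase=phase,
        status=status,
    )
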