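"""Shared fixtures: tiny record sets and the four-interaction ranking toy."""

import io

import pytest

import mirsig as m

#: Canonical toy record file: 3 studies, 2 diseases, dual and single values,
#: one row with no fold-change and one misformatted row (both droppable).
TOY_CSV = """\
study_id,pmid,disease,mirna,fc_min,fc_max
Study-1,p1,D1,M1,2.3,2.9
Study-1,p1,D1,M2,3.0,
Study-2,p2,D1,M1,1.5,2.5
Study-2,p2,D1,M2,6.7,6.7
Study-3,p3,D2,M1,4.0,
Study-3,p3,D2,M3,2.0,3.0
Study-3,p3,D2,M4,,
Study-3,p3,D2,M5,oops,
"""

#: Best-to-worst orders of the four-interaction worked example, one ranking
#: per fused algorithm.
RANKING_ORDERS = [
    ["I4", "I2", "I1", "I3"],
    ["I2", "I3", "I4", "I1"],
    ["I2", "I3", "I1", "I4"],
    ["I2", "I4", "I3", "I1"],
    ["I2", "I4", "I3", "I1"],
    ["I3", "I2", "I4", "I1"],
]


@pytest.fixture
def toy_dataset() -> m.Dataset:
    return m.parse_records(io.StringIO(TOY_CSV))


@pytest.fixture
def ranked_lists() -> list[m.RankedList]:
    return [
        m.ranked_list_from_order(f"alg{i}", order)
        for i, order in enumerate(RANKING_ORDERS, start=1)
    ]


@pytest.fixture
def small_synth() -> tuple[m.Dataset, m.GroundTruth, m.SynthConfig]:
    cfg = m.SynthConfig(
        n_mirnas=8,
        n_diseases=2,
        n_studies_per_disease=25,
        module_size=3,
        dual_value_fraction=0.4,
        missing_fraction=0.1,
        pmid_cocitation_rate=0.5,
        seed=11,
    )
    ds, gt = m.generate_dataset(cfg)
    return ds, gt, cfg
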