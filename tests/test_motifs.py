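"""Motif catalog initialization: versions, heterodimers, homologs."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from regprior import (
    MotifRecord,
    filter_heterodimers,
    initialize_catalog,
    resolve_homologs,
    select_newest_versions,
)


def rec(base_id, version, tf, species="human"):
    return MotifRecord(base_id, version, tf, species)


class TestNewestVersions:
    def test_newest_version_wins(self):
        cat = select_newest_versions(
            [rec("MA0898", 1, "Hmx3", "mouse"), rec("MA0898", 2, "Hmx3", "mouse")]
        )
        assert [r.motif_id for r in cat] == ["MA0898.2"]

    def test_max_per_accession(self):
        cat = select_newest_versions(
            [rec("X", 3, "A"), rec("X", 1, "A"), rec("Y", 1, "B")]
        )
        assert {r.motif_id for r in cat} == {"X.3", "Y.1"}

    def test_single_record_unchanged(self):
        cat = select_newest_versions([rec("X", 1, "A")])
        assert len(cat) == 1

    def test_duplicate_pair_is_error(self):
        with pytest.raises(ValueError, match="duplicate"):
            select_newest_versions([rec("X", 1, "A"), rec("X", 1, "A")])

    def test_idempotent(self):
        records = [rec("X", 3, "A"), rec("X", 1, "A"), rec("Y", 2, "B")]
        once = select_newest_versions(records)
        twice = select_newest_versions(once.records)
        assert once.records == twice.records


class TestHeterodimerFilter:
    def test_dimer_names_removed(self):
        cat = select_newest_versions([rec("X", 1, "FOS::JUN"), rec("Y", 1, "GATA1")])
        out = filter_heterodimers(cat, drop=True)
        assert out.tf_names == {"GATA1"}
        assert out.filters_applied[-1] == "drop_heterodimers"

    def test_drop_false_is_identity(self):
        cat = select_newest_versions([rec("X", 1, "FOS::JUN"), rec("Y", 1, "GATA1")])
        assert filter_heterodimers(cat, drop=False).records == cat.records

    def test_idempotent_and_no_op_without_dimers(self):
        cat = select_newest_versions([rec("Y", 1, "GATA1")])
        once = filter_heterodimers(cat, drop=True)
        assert once.records == cat.records
        assert filter_heterodimers(once, drop=True).records == once.records


class TestHomologResolution:
    def test_rename_when_no_human_record(self):
        cat = select_newest_versions([rec("MA0898", 2, "Hmx3", "mouse")])
        out, report = resolve_homologs(cat, {"Hmx3": "HMX3"})
        assert out.tf_names == {"HMX3"}
        assert report.renamed == {"Hmx3": "HMX3"}

    def test_human_version_preferred(self):
        cat = select_newest_versions(
            [rec("MA0001", 1, "HMX3", "human"), rec("MA0898", 2, "Hmx3", "mouse")]
        )
        out, report = resolve_homologs(cat, {"Hmx3": "HMX3"})
        assert [r.base_id for r in out] == ["MA0001"]
        assert report.dropped_human_preferred == ["Hmx3"]

    def test_no_homolog_discarded(self):
        cat = select_newest_versions([rec("MA0898", 2, "Hmx3", "mouse")])
        out, report = resolve_homologs(cat, {})
        assert len(out) == 0
        assert report.discarded_no_homolog == ["Hmx3"]

    def test_collision_keeps_newest_version(self):
        cat = select_newest_versions(
            [rec("MA0002", 1, "Hmx3", "mouse"), rec("MA0001", 3, "hmx3", "rat")]
        )
        out, report = resolve_homologs(cat, {"Hmx3": "HMX3", "hmx3": "HMX3"})
        assert len(out) == 1
        assert out.records[0].base_id == "MA0001"  # version 3 beats version 1
        assert report.collisions == ["HMX3"]

    def test_unique_names_after_full_chain(self):
        records = [
            rec("MA0001", 2, "GATA1"),
            rec("MA0001", 1, "GATA1"),
            rec("MA0002", 1, "FOS::JUN"),
            rec("MA0003", 1, "Hmx3", "mouse"),
            rec("MA0004", 1, "Vrt9", "mouse"),
        ]
        cat, _ = initialize_catalog(records, {"Hmx3": "HMX3"})
        names = [r.tf_name for r in cat]
        assert sorted(names) == sorted(set(names)) == ["GATA1", "HMX3"]


@settings(derandomize=True, max_examples=50)
@given(
    st.lists(
        st.tuples(
            st.sampled_from(["MA1", "MA2", "MA3", "MA4"]),
            st.integers(min_value=1, max_value=5),
            st.sampled_from(["TFA", "TFB", "A::B", "Xyz"]),
            st.sampled_from(["human", "mouse"]),
        ),
        unique_by=lambda x: (x[0], x[1]),
        max_size=12,
    )
)
def test_catalog_size_non_increasing_through_filters(raw):
    """Every initialization step can only shrink the catalog."""
    records = [MotifRecord(*r) for r in raw]
    newest = select_newest_versions(records)
    assert len(newest) <= len(records)
    nodimers = filter_heterodimers(newest, drop=True)
    assert len(nodimers) <= len(newest)
    resolved, _ = resolve_homologs(nodimers, {"Xyz": "TFA"})
    assert len(resolved) <= len(nodimers)
    # unique resolved names
    assert len({r.tf_name for r in resolved}) == len(resolved)
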