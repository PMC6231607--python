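"""Canonical-file reading, validation diagnostics, archive adapter, exports."""

import zipfile

import pandas as pd
import pytest

from tomonet import (
    Bin,
    SchemaError,
    export_signed_network,
    import_signed_network,
    read_reports,
    read_supplementary_archive,
    write_reports,
)
from tomonet.simulate import NullSimConfig, simulate_null_reports
from tomonet.ties import PairEvidence, SignedNetwork

from conftest import FIXTURE_B, FIXTURE_K, REPORTS_CSV


def test_fixture_loads_with_hand_counted_degrees(tiny_reports):
    assert tiny_reports.m == 3
    assert tiny_reports.n == 5
    degrees = {r.respondent_id: r.recognition_degree for r in tiny_reports.reports}
    assert degrees == {"A": 2, "B": 3, "C": 2}
    # own photo shown to C carries no entries
    rep_c = next(r for r in tiny_reports.reports if r.respondent_id == "C")
    assert "C" in rep_c.shown and "C" not in rep_c.bin


def test_bin_partition_covers_shown_minus_self(tiny_reports):
    for rep in tiny_reports.reports:
        shown_minus_self = set(rep.shown) - {rep.respondent_id}
        assert set(rep.bin) == shown_minus_self
        sizes = {b: sum(1 for x in rep.bin.values() if x is b) for b in Bin}
        assert sum(sizes.values()) == len(shown_minus_self)


def test_empty_reports_file_yields_m_zero(canonical_dir):
    (canonical_dir / "reports.csv").write_text("respondent_id,member_id,bin,cluster\n")
    (canonical_dir / "opinions.csv").write_text(
        "respondent_id,member_id,attribute_id,opinion\n"
    )
    rs = read_reports(
        canonical_dir / "roster.csv",
        canonical_dir / "attributes.csv",
        canonical_dir / "reports.csv",
        canonical_dir / "opinions.csv",
        b_clusters=FIXTURE_B,
    )
    assert rs.m == 0


@pytest.mark.parametrize(
    "bad_line, fragment",
    [
        ("C,E,recognized,6", "outside 1..3"),          # cluster beyond B
        ("A,B,recognized,1", "duplicate"),             # repeated (respondent, member)
        ("A,Z,recognized,1", "unknown member"),        # id not on roster
        ("C,E,unknown,2", "non-recognized"),           # cluster without recognition
    ],
)
def test_malformed_rows_are_located(canonical_dir, bad_line, fragment):
    (canonical_dir / "reports.csv").write_text(REPORTS_CSV + bad_line + "\n")
    with pytest.raises(SchemaError) as err:
        read_reports(
            canonical_dir / "roster.csv",
            canonical_dir / "attributes.csv",
            canonical_dir / "reports.csv",
            canonical_dir / "opinions.csv",
            b_clusters=FIXTURE_B,
            k=FIXTURE_K,
        )
    assert any(fragment in d and "row 13" in d for d in err.value.diagnostics)


def test_opinion_for_unrecognized_member_rejected(canonical_dir):
    with open(canonical_dir / "opinions.csv", "a") as fh:
        fh.write("A,E,X1,1\n")  # E is in A's UNKNOWN bin
    with pytest.raises(SchemaError, match="non-RECOGNIZED"):
        read_reports(
            canonical_dir / "roster.csv",
            canonical_dir / "attributes.csv",
            canonical_dir / "reports.csv",
            canonical_dir / "opinions.csv",
            b_clusters=FIXTURE_B,
            k=FIXTURE_K,
        )


def test_write_read_round_trip_is_lossless(tiny_reports, tmp_path):
    paths = write_reports(tiny_reports, tmp_path / "out")
    back = read_reports(
        paths["roster"], paths["attributes"], paths["reports"], paths["opinions"],
        b_clusters=FIXTURE_B, k=FIXTURE_K,
    )
    assert back.roster == tiny_reports.roster
    assert back.attributes == tiny_reports.attributes
    orig = {r.respondent_id: r for r in tiny_reports.reports}
    for rep in back.reports:
        ref = orig[rep.respondent_id]
        assert set(rep.shown) == set(ref.shown)
        assert rep.bin == ref.bin
        assert rep.cluster == ref.cluster
        assert rep.opinions == ref.opinions


def _zip_canonical(canonical_dir, zip_path, renames=None, skip=()):
    renames = renames or {}
    with zipfile.ZipFile(zip_path, "w") as zf:
        for name in ("roster", "attributes", "reports", "opinions"):
            if name in skip:
                continue
            df = pd.read_csv(canonical_dir / f"{name}.csv", dtype=str)
            df = df.rename(columns=renames.get(name, {}))
            zf.writestr(f"{name}.csv", df.to_csv(index=False))


def _identity_mapping(tmp_path, skip=()):
    import yaml

    cfg = {
        "b_clusters": FIXTURE_B,
        "k": FIXTURE_K,
        "roster": {"file": "roster.csv"},
        "attributes": {"file": "attributes.csv"},
        "reports": {"file": "reports.csv"},
        "opinions": {"file": "opinions.csv"},
    }
    for name in skip:
        cfg.pop(name)
    path = tmp_path / "mapping.yaml"
    path.write_text(yaml.safe_dump(cfg))
    return path


def test_archive_identity_mapping_matches_direct_read(canonical_dir, tiny_reports, tmp_path):
    zip_path = tmp_path / "study.zip"
    _zip_canonical(canonical_dir, zip_path)
    rs = read_supplementary_archive(zip_path, _identity_mapping(tmp_path))
    assert rs.m == tiny_reports.m
    assert {r.respondent_id: r.cluster for r in rs.reports} == {
        r.respondent_id: r.cluster for r in tiny_reports.reports
    }
    assert {r.respondent_id: r.opinions for r in rs.reports} == {
        r.respondent_id: r.opinions for r in tiny_reports.reports
    }


def test_archive_with_renamed_columns(canonical_dir, tiny_reports, tmp_path):
    import yaml

    zip_path = tmp_path / "study.zip"
    _zip_canonical(
        canonical_dir, zip_path,
        renames={"reports": {"respondent_id": "resp", "member_id": "photo", "bin": "sorted_to"}},
    )
    cfg = {
        "b_clusters": FIXTURE_B,
        "k": FIXTURE_K,
        "roster": {"file": "roster.csv"},
        "attributes": {"file": "attributes.csv"},
        "reports": {
            "file": "reports.csv",
            "respondent_id": "resp",
            "member_id": "photo",
            "bin": "sorted_to",
        },
        "opinions": {"file": "opinions.csv"},
    }
    mapping = tmp_path / "mapping.yaml"
    mapping.write_text(yaml.safe_dump(cfg))
    rs = read_supplementary_archive(zip_path, mapping)
    assert {r.respondent_id: r.bin for r in rs.reports} == {
        r.respondent_id: r.bin for r in tiny_reports.reports
    }


def test_archive_without_opinions_warns_and_loads_empty(canonical_dir, tmp_path, caplog):
    zip_path = tmp_path / "study.zip"
    _zip_canonical(canonical_dir, zip_path, skip=("opinions",))
    with caplog.at_level("WARNING"):
        rs = read_supplementary_archive(zip_path, _identity_mapping(tmp_path, skip=("opinions",)))
    assert all(not r.opinions for r in rs.reports)
    assert any("opinions" in rec.message for rec in caplog.records)


def test_archive_unmapped_required_field_fails(canonical_dir, tmp_path):
    zip_path = tmp_path / "study.zip"
    _zip_canonical(canonical_dir, zip_path, renames={"reports": {"bin": "mystery"}})
    with pytest.raises(ValueError, match="unmapped required field 'bin'"):
        read_supplementary_archive(zip_path, _identity_mapping(tmp_path))


def _toy_network():
    edges = {("n1", "n2"): +1, ("n2", "n3"): -1}
    ev = {
        pair: PairEvidence(pair=pair, n_corecognized=3, x_obs=3 if s > 0 else 0,
                           y_obs=0 if s > 0 else 3)
        for pair, s in edges.items()
    }
    return SignedNetwork(
        nodes=frozenset({"n1", "n2", "n3", "lone"}),
        edges=edges,
        contested=frozenset(),
        evidence=ev,
    )


def test_pajek_export_has_signed_edge_lines(tmp_path):
    path = export_signed_network(_toy_network(), "pajek_net", tmp_path / "net.net")
    lines = path.read_text().splitlines()
    assert lines[0] == "*Vertices 4"
    edge_lines = lines[lines.index("*Edges") + 1 :]
    weights = sorted(int(l.split()[2]) for l in edge_lines)
    assert weights == [-1, 1]
    # the isolated node appears in the vertex section only
    assert any('"lone"' in l for l in lines[1:5])


@pytest.mark.parametrize("fmt", ["pajek_net", "graphml", "edge_csv"])
def test_export_import_round_trip(fmt, tmp_path):
    cfg = NullSimConfig(n=50, m=30, k=12, b_clusters=2, gamma=0.8, seed=7)
    reports = simulate_null_reports(cfg)
    from tomonet import infer_from_reports

    net = infer_from_reports(reports, 2, 3)
    assert net.edges, "fixture should produce at least one edge"
    path = export_signed_network(net, fmt, tmp_path / "net.out")
    back = import_signed_network(fmt, path)
    assert dict(back.edges) == dict(net.edges)


def test_unknown_export_format_rejected(tmp_path):
    with pytest.raises(ValueError, match="unknown format"):
        export_signed_network(_toy_network(), "gexf", tmp_path / "x")
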