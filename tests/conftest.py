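"""Shared fixtures: a hand-built three-respondent study and its canonical CSVs."""

from __future__ import annotations

import textwrap

import pytest

from tomonet import read_reports

ROSTER_CSV = textwrap.dedent(
    """\
    member_id,label
    A,Alice
    B,Bert
    C,Cora
    D,Dale
    E,Edie
    """
)

ATTRIBUTES_CSV = textwrap.dedent(
    """\
    attribute_id,description
    X1,helps neighbours
    X2,gives good advice
    """
)

# respondent C was shown their own photo; it carries no bin/cluster entries
REPORTS_CSV = textwrap.dedent(
    """\
    respondent_id,member_id,bin,cluster
    A,B,recognized,1
    A,C,recognized,1
    A,D,close,
    A,E,unknown,
    B,A,recognized,2
    B,C,recognized,3
    B,D,recognized,2
    B,E,unknown,
    C,A,recognized,1
    C,B,recognized,1
    C,D,unknown,
    C,C,,
    """
)

OPINIONS_CSV = textwrap.dedent(
    """\
    respondent_id,member_id,attribute_id,opinion
    A,B,X1,1
    A,C,X1,0
    A,B,X2,1
    A,C,X2,1
    B,A,X1,1
    B,C,X1,1
    B,D,X1,0
    C,A,X1,0
    C,B,X2,0
    """
)

# hand-tallied facts about the fixture, used across test modules:
#   d = (A:2, B:3, C:2); gamma = 7 / (3*4)
#   pair evidence: (B,C) x=1; (A,C) y=1; (A,D) x=1; (C,D) y=1; (A,B) x=1
#   observer sets: O_A={B,C} O_B={A,C} O_C={A,B} O_D={B} O_E={}
#   beta_X1 = 3/6, beta_X2 = 2/3
FIXTURE_K = 4
FIXTURE_B = 3


@pytest.fixture
def canonical_dir(tmp_path):
    (tmp_path / "roster.csv").write_text(ROSTER_CSV)
    (tmp_path / "attributes.csv").write_text(ATTRIBUTES_CSV)
    (tmp_path / "reports.csv").write_text(REPORTS_CSV)
    (tmp_path / "opinions.csv").write_text(OPINIONS_CSV)
    return tmp_path


@pytest.fixture
def tiny_reports(canonical_dir):
    return read_reports(
        canonical_dir / "roster.csv",
        canonical_dir / "attributes.csv",
        canonical_dir / "reports.csv",
        canonical_dir / "opinions.csv",
        b_clusters=FIXTURE_B,
        k=FIXTURE_K,
    )
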