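"""Data model and file formats for photo-binning survey studies.

A study elicits perceptions of a population ``P`` of ``n`` photographed
individuals.  Each sampled respondent is shown ``k`` photos and sorts them
into three bins — CLOSE ("close to me"), RECOGNIZED ("not close but I
recognize"), UNKNOWN — then groups the RECOGNIZED members into up to ``B``
clusters of people perceived to be close to one another, and finally gives a
binary opinion on each of ``M`` attributes for every RECOGNIZED member.

Canonical on-disk representation is four CSV files::

    roster.csv      member_id,label
    attributes.csv  attribute_id,description
    reports.csv     respondent_id,member_id,bin,cluster
    opinions.csv    respondent_id,member_id,attribute_id,opinion

``bin`` is one of ``close``/``recognized``/``unknown``; ``cluster`` is an
integer in ``1..B`` for recognized members (empty otherwise); ``opinion`` is
0/1.  Signed networks export to Pajek NET, GraphML, or a plain edge CSV;
partitions export to Pajek CLU.
"""

from __future__ import annotations

import csv
import io as _io
import logging
import zipfile
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "Bin",
    "Roster",
    "AttributeCatalog",
    "Report",
    "ReportSet",
    "SchemaError",
    "read_reports",
    "write_reports",
    "read_supplementary_archive",
    "export_signed_network",
    "import_signed_network",
    "write_partition_clu",
]


class Bin(str, Enum):
    """The three sorting bins offered to a respondent."""

    CLOSE = "close"
    RECOGNIZED = "recognized"
    UNKNOWN = "unknown"


class SchemaError(ValueError):
    """Raised when input files violate the canonical schema.

    ``diagnostics`` holds one located message per malformed row.
    """

    def __init__(self, diagnostics: list[str]):
        self.diagnostics = list(diagnostics)
        super().__init__(
            f"{len(self.diagnostics)} schema violation(s):\n"
            + "\n".join(self.diagnostics)
        )


@dataclass(frozen=True)
class Roster:
    """The population P: unique member identifiers, optional display labels."""

    members: tuple[str, ...]
    labels: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.members)) != len(self.members):
            raise ValueError("roster identifiers must be unique")
        if len(self.members) < 2:
            raise ValueError("roster needs at least 2 members")

    @property
    def n(self) -> int:
        return len(self.members)

    def __contains__(self, member: str) -> bool:
        return member in set(self.members)


@dataclass(frozen=True)
class AttributeCatalog:
    """Ordered catalog of the M binary attributes under study."""

    attributes: tuple[str, ...]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if len(self.attributes) < 1:
            raise ValueError("need at least one attribute")
        if len(set(self.attributes)) != len(self.attributes):
            raise ValueError("attribute identifiers must be unique")

    @property
    def m_attrs(self) -> int:
        return len(self.attributes)


@dataclass
class Report:
    """One respondent's binning, clustering, and opinions on the shown photos.

    ``cluster`` maps RECOGNIZED members to an integer in ``1..B``;
    ``opinions`` maps ``(member, attribute)`` to 0/1 and is defined only for
    RECOGNIZED members.  If the respondent's own photo was shown it carries no
    bin/cluster/opinion entries.
    """

    respondent_id: str
    shown: tuple[str, ...]
    bin: dict[str, Bin]
    cluster: dict[str, int]
    opinions: dict[tuple[str, str], int]

    @property
    def recognized(self) -> list[str]:
        return [v for v, b in self.bin.items() if b is Bin.RECOGNIZED]

    @property
    def recognition_degree(self) -> int:
        """d(s_i): the size of the RECOGNIZED bin."""
        return len(self.recognized)

    def validate(self, roster: Roster, b_clusters: int, strict: bool = True) -> list[str]:
        """Return a list of invariant-violation messages (empty when valid)."""
        problems: list[str] = []
        who = f"respondent {self.respondent_id!r}"
        if len(set(self.shown)) != len(self.shown):
            problems.append(f"{who}: duplicate members in shown set")
        shown = set(self.shown)
        if self.respondent_id in self.bin:
            problems.append(f"{who}: own photo carries a bin entry")
        for v in self.bin:
            if v not in shown:
                problems.append(f"{who}: bin entry for non-shown member {v!r}")
            if v not in roster:
                problems.append(f"{who}: unknown member id {v!r}")
        recognized = set(self.recognized)
        for v, c in self.cluster.items():
            if v not in recognized:
                problems.append(f"{who}: cluster for non-RECOGNIZED member {v!r}")
            elif not (1 <= c <= b_clusters):
                problems.append(
                    f"{who}: cluster {c} for member {v!r} outside 1..{b_clusters}"
                )
        if strict:
            for v in sorted(recognized - set(self.cluster)):
                problems.append(f"{who}: RECOGNIZED member {v!r} has no cluster")
        for (v, _a), o in self.opinions.items():
            if v not in recognized:
                problems.append(f"{who}: opinion on non-RECOGNIZED member {v!r}")
            if o not in (0, 1):
                problems.append(f"{who}: opinion on {v!r} not in {{0,1}}")
        return problems


@dataclass
class ReportSet:
    """A validated collection of reports plus the study parameters (n, k, B, M)."""

    roster: Roster
    attributes: AttributeCatalog
    reports: list[Report]
    k: int
    b_clusters: int

    @property
    def n(self) -> int:
        return self.roster.n

    @property
    def m(self) -> int:
        """Number of reports (the sample size)."""
        return len(self.reports)

    def validate(self, strict: bool = True) -> None:
        """Raise :class:`SchemaError` collecting every invariant violation."""
        problems: list[str] = []
        seen = set()
        for rep in self.reports:
            if rep.respondent_id in seen:
                problems.append(f"duplicate report for respondent {rep.respondent_id!r}")
            seen.add(rep.respondent_id)
            if strict and len(set(rep.shown) - {rep.respondent_id}) + (
                rep.respondent_id in rep.shown
            ) != len(rep.shown):
                pass  # duplicate-shown caught inside Report.validate
            if strict and len(rep.shown) != self.k:
                problems.append(
                    f"respondent {rep.respondent_id!r}: shown {len(rep.shown)} "
                    f"members, expected k={self.k}"
                )
            problems.extend(rep.validate(self.roster, self.b_clusters, strict=strict))
        if problems:
            raise SchemaError(problems)


# ---------------------------------------------------------------------------
# canonical CSV reading / writing
# ---------------------------------------------------------------------------

_BIN_TOKENS = {b.value: b for b in Bin}


def _read_roster_frame(df: pd.DataFrame) -> Roster:
    members = tuple(df["member_id"].astype(str))
    labels = {}
    if "label" in df.columns:
        labels = dict(zip(members, df["label"].fillna("").astype(str)))
    return Roster(members=members, labels=labels)


def _read_attributes_frame(df: pd.DataFrame) -> AttributeCatalog:
    attrs = tuple(df["attribute_id"].astype(str))
    desc = {}
    if "description" in df.columns:
        desc = dict(zip(attrs, df["description"].fillna("").astype(str)))
    return AttributeCatalog(attributes=attrs, descriptions=desc)


def _assemble(
    roster: Roster,
    catalog: AttributeCatalog,
    reports_df: pd.DataFrame,
    opinions_df: pd.DataFrame | None,
    k: int | None,
    b_clusters: int,
    strict: bool,
) -> ReportSet:
    """Build and validate a ReportSet from canonical-schema dataframes.

    Row numbers in diagnostics are 1-based data rows (header excluded).
    """
    problems: list[str] = []
    reports: dict[str, Report] = {}
    pair_rows: set[tuple[str, str]] = set()
    member_set = set(roster.members)

    for idx, row in enumerate(reports_df.itertuples(index=False), start=1):
        rid = str(row.respondent_id)
        mid = str(row.member_id)
        where = f"reports.csv row {idx}"
        if rid not in member_set:
            problems.append(f"{where}: unknown respondent id {rid!r}")
            continue
        if mid not in member_set:
            problems.append(f"{where}: unknown member id {mid!r}")
            continue
        if (rid, mid) in pair_rows:
            problems.append(f"{where}: duplicate (respondent, member) row ({rid!r}, {mid!r})")
            continue
        pair_rows.add((rid, mid))
        rep = reports.setdefault(
            rid, Report(respondent_id=rid, shown=(), bin={}, cluster={}, opinions={})
        )
        rep.shown = rep.shown + (mid,)
        if mid == rid:
            # own photo: shown but never binned/clustered
            continue
        token = str(row.bin).strip().lower()
        if token not in _BIN_TOKENS:
            problems.append(f"{where}: unknown bin token {row.bin!r}")
            continue
        b = _BIN_TOKENS[token]
        rep.bin[mid] = b
        raw_cluster = getattr(row, "cluster", None)
        has_cluster = raw_cluster is not None and not pd.isna(raw_cluster) and str(raw_cluster).strip() != ""
        if has_cluster:
            try:
                c = int(float(raw_cluster))
            except ValueError:
                problems.append(f"{where}: non-integer cluster {raw_cluster!r}")
                continue
            if b is not Bin.RECOGNIZED:
                problems.append(f"{where}: cluster given for non-recognized member {mid!r}")
                continue
            if not (1 <= c <= b_clusters):
                problems.append(f"{where}: cluster {c} outside 1..{b_clusters}")
                continue
            rep.cluster[mid] = c
        elif b is Bin.RECOGNIZED and strict:
            problems.append(f"{where}: recognized member {mid!r} has no cluster")

    if opinions_df is not None:
        attr_set = set(catalog.attributes)
        seen_op: set[tuple[str, str, str]] = set()
        for idx, row in enumerate(opinions_df.itertuples(index=False), start=1):
            rid, mid, aid = str(row.respondent_id), str(row.member_id), str(row.attribute_id)
            where = f"opinions.csv row {idx}"
            if rid not in reports:
                problems.append(f"{where}: opinion from unknown respondent {rid!r}")
                continue
            if aid not in attr_set:
                problems.append(f"{where}: unknown attribute id {aid!r}")
                continue
            if (rid, mid, aid) in seen_op:
                problems.append(f"{where}: duplicate opinion row")
                continue
            seen_op.add((rid, mid, aid))
            rep = reports[rid]
            if rep.bin.get(mid) is not Bin.RECOGNIZED:
                problems.append(f"{where}: opinion for non-RECOGNIZED member {mid!r}")
                continue
            try:
                o = int(row.opinion)
            except (TypeError, ValueError):
                o = -999
            if o not in (0, 1):
                problems.append(f"{where}: opinion {row.opinion!r} not in {{0,1}}")
                continue
            rep.opinions[(mid, aid)] = o

    if problems:
        raise SchemaError(problems)

    if not strict:
        # lenient mode: drop recognized-but-unclustered members from the
        # RECOGNIZED bin so they never enter pair tallies
        for rep in reports.values():
            for v in list(rep.bin):
                if rep.bin[v] is Bin.RECOGNIZED and v not in rep.cluster:
                    del rep.bin[v]

    report_list = list(reports.values())
    if k is None:
        k = len(report_list[0].shown) if report_list else 0
    rs = ReportSet(
        roster=roster, attributes=catalog, reports=report_list, k=k, b_clusters=b_clusters
    )
    rs.validate(strict=strict)
    return rs


def read_reports(
    roster_file: str | Path,
    attributes_file: str | Path,
    reports_file: str | Path,
    opinions_file: str | Path | None,
    *,
    b_clusters: int = 5,
    k: int | None = None,
    strict: bool = True,
) -> ReportSet:
    """Read the four canonical CSV files into a validated :class:`ReportSet`.

    ``k`` defaults to the shown-set size of the first report.  In strict mode
    every RECOGNIZED member must carry a cluster and every report must show
    exactly ``k`` members; lenient mode drops unclustered RECOGNIZED members
    from tallies and allows varying ``k``.
    """
    roster = _read_roster_frame(pd.read_csv(roster_file, dtype=str))
    catalog = _read_attributes_frame(pd.read_csv(attributes_file, dtype=str))
    reports_df = pd.read_csv(reports_file, dtype=str)
    opinions_df = pd.read_csv(opinions_file, dtype=str) if opinions_file else None
    if opinions_df is not None and opinions_df.empty:
        opinions_df = None
    return _assemble(roster, catalog, reports_df, opinions_df, k, b_clusters, strict)


def write_reports(reports: ReportSet, out_dir: str | Path) -> dict[str, Path]:
    """Write a ReportSet back to the four canonical CSVs. Lossless round trip."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "roster": out / "roster.csv",
        "attributes": out / "attributes.csv",
        "reports": out / "reports.csv",
        "opinions": out / "opinions.csv",
    }
    pd.DataFrame(
        {
            "member_id": reports.roster.members,
            "label": [reports.roster.labels.get(v, "") for v in reports.roster.members],
        }
    ).to_csv(paths["roster"], index=False)
    pd.DataFrame(
        {
            "attribute_id": reports.attributes.attributes,
            "description": [
                reports.attributes.descriptions.get(a, "")
                for a in reports.attributes.attributes
            ],
        }
    ).to_csv(paths["attributes"], index=False)
    rep_rows, op_rows = [], []
    for rep in reports.reports:
        for mid in rep.shown:
            if mid == rep.respondent_id:
                rep_rows.append((rep.respondent_id, mid, "", ""))
                continue
            b = rep.bin[mid]
            c = rep.cluster.get(mid, "")
            rep_rows.append((rep.respondent_id, mid, b.value, c))
        for (mid, aid), o in sorted(rep.opinions.items()):
            op_rows.append((rep.respondent_id, mid, aid, o))
    pd.DataFrame(
        rep_rows, columns=["respondent_id", "member_id", "bin", "cluster"]
    ).to_csv(paths["reports"], index=False)
    pd.DataFrame(
        op_rows, columns=["respondent_id", "member_id", "attribute_id", "opinion"]
    ).to_csv(paths["opinions"], index=False)
    return paths


# ---------------------------------------------------------------------------
# supplementary-archive adapter
# ---------------------------------------------------------------------------

def read_supplementary_archive(
    zip_path: str | Path,
    mapping_config: str | Path,
    *,
    strict: bool = True,
) -> ReportSet:
    """Ingest a deposited study archive through a user-supplied column mapping.

    The YAML mapping names, for each canonical table, the file inside the zip
    and the source column for each canonical field, e.g.::

        b_clusters: 5
        roster:  {file: roster.csv, member_id: id, label: name}
        reports: {file: reports.csv, respondent_id: resp, member_id: photo,
                  bin: bin, cluster: cluster,
                  bin_values: {close: c1, recognized: c2, unknown: c3}}
        attributes: {file: attributes.csv, attribute_id: attribute_id}
        opinions:   {file: opinions.csv, respondent_id: respondent_id, ...}

    ``opinions`` (and ``attributes``) may be omitted, yielding a ReportSet with
    empty opinions and a logged warning.  ``bin_values`` optionally translates
    archive-specific bin tokens onto close/recognized/unknown.
    """
    with open(mapping_config) as fh:
        cfg = yaml.safe_load(fh)
    for required in ("roster", "reports"):
        if required not in cfg:
            raise ValueError(f"mapping config missing required section {required!r}")

    def load(section: dict, fields: dict[str, bool]) -> pd.DataFrame:
        try:
            with zf.open(section["file"]) as fh:
                df = pd.read_csv(_io.TextIOWrapper(fh, encoding="utf-8"), dtype=str)
        except KeyError as exc:
            raise ValueError(f"archive has no file {section['file']!r}") from exc
        rename = {}
        for canonical, required in fields.items():
            src = section.get(canonical, canonical if canonical in df.columns else None)
            if src is None or src not in df.columns:
                if required:
                    raise ValueError(
                        f"unmapped required field {canonical!r} for {section['file']!r}"
                    )
                continue
            rename[src] = canonical
        return df.rename(columns=rename)

    with zipfile.ZipFile(zip_path) as zf:
        roster = _read_roster_frame(load(cfg["roster"], {"member_id": True, "label": False}))
        reports_df = load(
            cfg["reports"],
            {"respondent_id": True, "member_id": True, "bin": True, "cluster": False},
        )
        bin_values = cfg["reports"].get("bin_values")
        if bin_values:
            reverse = {str(v).lower(): k for k, v in bin_values.items()}
            reports_df["bin"] = reports_df["bin"].str.lower().map(reverse).fillna(
                reports_df["bin"]
            )
        if "attributes" in cfg:
            catalog = _read_attributes_frame(
                load(cfg["attributes"], {"attribute_id": True, "description": False})
            )
        else:
            catalog = AttributeCatalog(attributes=("__none__",))
        opinions_df = None
        if "opinions" in cfg:
            opinions_df = load(
                cfg["opinions"],
                {
                    "respondent_id": True,
                    "member_id": True,
                    "attribute_id": True,
                    "opinion": True,
                },
            )
        else:
            logger.warning(
                "mapping config declares no opinions table; opinions left empty"
            )
    return _assemble(
        roster,
        catalog,
        reports_df,
        opinions_df,
        cfg.get("k"),
        int(cfg.get("b_clusters", 5)),
        strict,
    )


# ---------------------------------------------------------------------------
# network / partition exports
# ---------------------------------------------------------------------------

def export_signed_network(network, fmt: str, path: str | Path) -> Path:
    """Write a signed network as Pajek NET, GraphML, or a plain edge CSV.

    Pajek NET uses ``*Vertices``/``*Edges`` with edge weight +1/-1; GraphML
    carries an integer ``sign`` attribute; the edge CSV carries
    ``u,v,sign,x_obs,y_obs``.  :func:`import_signed_network` inverts all
    three losslessly (the CSV keeps evidence counts; NET/GraphML keep the
    node set and signed edges).
    """
    if not network.nodes:
        raise ValueError("cannot export an empty network")
    path = Path(path)
    nodes = sorted(network.nodes)
    index = {v: i + 1 for i, v in enumerate(nodes)}
    if fmt == "pajek_net":
        with open(path, "w", newline="\n") as fh:
            fh.write(f"*Vertices {len(nodes)}\n")
            for v in nodes:
                fh.write(f'{index[v]} "{v}"\n')
            fh.write("*Edges\n")
            for (u, v), sign in sorted(network.edges.items()):
                fh.write(f"{index[u]} {index[v]} {sign}\n")
    elif fmt == "graphml":
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for (u, v), sign in network.edges.items():
            g.add_edge(u, v, sign=int(sign))
        nx.write_graphml(g, path)
    elif fmt == "edge_csv":
        rows = []
        for (u, v), sign in sorted(network.edges.items()):
            ev = network.evidence.get((u, v))
            rows.append(
                (u, v, sign, ev.x_obs if ev else "", ev.y_obs if ev else "")
            )
        pd.DataFrame(rows, columns=["u", "v", "sign", "x_obs", "y_obs"]).to_csv(
            path, index=False
        )
    else:
        raise ValueError(f"unknown format token {fmt!r}")
    return path


def import_signed_network(fmt: str, path: str | Path):
    """Read a signed network previously written by :func:`export_signed_network`."""
    from .ties import PairEvidence, SignedNetwork  # local import to avoid a cycle

    path = Path(path)
    nodes: list[str] = []
    edges: dict[tuple[str, str], int] = {}
    evidence: dict[tuple[str, str], PairEvidence] = {}
    if fmt == "pajek_net":
        with open(path) as fh:
            section = None
            idx_to_node: dict[int, str] = {}
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                low = line.lower()
                if low.startswith("*vertices"):
                    section = "v"
                    continue
                if low.startswith("*edges") or low.startswith("*arcs"):
                    section = "e"
                    continue
                parts = next(csv.reader([line], delimiter=" ", skipinitialspace=True))
                if section == "v":
                    idx_to_node[int(parts[0])] = parts[1]
                elif section == "e":
                    u, v = idx_to_node[int(parts[0])], idx_to_node[int(parts[1])]
                    edges[tuple(sorted((u, v)))] = int(float(parts[2]))
            nodes = list(idx_to_node.values())
    elif fmt == "graphml":
        g = nx.read_graphml(path)
        nodes = list(g.nodes)
        for u, v, d in g.edges(data=True):
            edges[tuple(sorted((u, v)))] = int(d["sign"])
    elif fmt == "edge_csv":
        df = pd.read_csv(path, dtype={"u": str, "v": str})
        seen = set()
        for row in df.itertuples(index=False):
            pair = tuple(sorted((row.u, row.v)))
            edges[pair] = int(row.sign)
            seen.update(pair)
            if not pd.isna(row.x_obs):
                x, y = int(row.x_obs), int(row.y_obs)
                evidence[pair] = PairEvidence(
                    pair=pair, n_corecognized=x + y, x_obs=x, y_obs=y
                )
        nodes = sorted(seen)
    else:
        raise ValueError(f"unknown format token {fmt!r}")
    return SignedNetwork(
        nodes=frozenset(nodes), edges=edges, contested=frozenset(), evidence=evidence
    )


def write_partition_clu(assignment: Mapping[str, int], nodes: Iterable[str], path: str | Path) -> Path:
    """Write a Pajek CLU file for ``nodes`` in sorted order."""
    path = Path(path)
    ordered = sorted(nodes)
    with open(path, "w", newline="\n") as fh:
        fh.write(f"*Vertices {len(ordered)}\n")
        for v in ordered:
            fh.write(f"{assignment[v]}\n")
    return path
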