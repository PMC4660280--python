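"""PSI-MI TAB (MITAB) parsing, curation and graph construction.

The interactome analysed by the pipeline arrives as a MITAB 2.5/2.6/2.7
tab-separated table (iRefIndex-style).  This module parses it into
:class:`InteractionRecord` rows, applies the curation used to build the
human experimental interactome — keep only records where both interactors
are the required taxon, drop computationally predicted interactions, drop
self-interactions — and converts the surviving records into a simple
undirected :class:`~deltabc.network.ProteinNetwork`.

Missing fields are written ``"-"`` in MITAB; lines starting with ``"#"`` are
comments (iRefIndex writes its header that way).  Only a handful of the 36+
columns matter here, and their positions are configurable through
:class:`MitabDialect`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .errors import MitabError
from .network import ProteinNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_PREDICTED_CODES",
    "MitabDialect",
    "InteractionRecord",
    "CurationPolicy",
    "CurationReport",
    "parse_mitab",
    "curate",
    "curate_with_report",
    "build_graph",
]

#: Curated snapshot of the PSI-MI "interaction prediction" branch (MI:0063
#: and its descendants).  Records whose interaction-detection method carries
#: one of these codes are treated as computational predictions rather than
#: experimental observations.  Override through :class:`CurationPolicy`.
DEFAULT_PREDICTED_CODES: frozenset[str] = frozenset(
    {
        "MI:0063",  # interaction prediction
        "MI:0036",  # domain fusion
        "MI:0057",  # gene neighbourhood
        "MI:0058",  # genome based prediction
        "MI:0064",  # interologs mapping
        "MI:0085",  # phylogenetic profile
        "MI:0087",  # predictive text mining
        "MI:0101",  # sequence based prediction
        "MI:0105",  # structure based prediction
    }
)

_TAXID_RE = re.compile(r"taxid:(-?\d+)")
_MI_CODE_RE = re.compile(r"MI:\d{4}")


@dataclass(frozen=True)
class MitabDialect:
    """Column mapping for a MITAB flavour.

    Defaults follow the common 2.5/2.6/2.7 layout: interactor uids in
    columns 0-1, alternative ids in 2-3, aliases in 4-5, detection method in
    6, taxa in 9-10.
    """

    col_uid_a: int = 0
    col_uid_b: int = 1
    col_alt_a: int = 2
    col_alt_b: int = 3
    col_alias_a: int = 4
    col_alias_b: int = 5
    col_method: int = 6
    col_taxid_a: int = 9
    col_taxid_b: int = 10
    #: Skip the first non-comment line even if it does not start with "#".
    skip_header: bool = False

    @property
    def min_columns(self) -> int:
        return 1 + max(
            self.col_uid_a,
            self.col_uid_b,
            self.col_alt_a,
            self.col_alt_b,
            self.col_alias_a,
            self.col_alias_b,
            self.col_method,
            self.col_taxid_a,
            self.col_taxid_b,
        )


@dataclass(frozen=True)
class InteractionRecord:
    """One parsed MITAB row.

    ``uid_a``/``uid_b`` are the raw interactor uids (database prefix
    stripped); ``alias_a``/``alias_b`` the preferred-name aliases when
    present; taxa and detection method are ``None`` when the field was
    missing (``"-"``).  ``source_line`` is the 1-based line number in the
    parsed file and uniquely indexes the record.
    """

    uid_a: str
    uid_b: str
    alias_a: str | None
    alias_b: str | None
    taxid_a: int | None
    taxid_b: int | None
    detection_method: str | None
    source_line: int

    def identifier(self, side: str, preference: Sequence[str] = ("alias", "uid")) -> str:
        """Resolve the node identifier for interactor ``side`` ("a"/"b").

        ``preference`` is tried in order; ``"alias"`` uses the alias column,
        ``"uid"`` the raw uid.  The raw uid is the final fallback, so two
        raw uids are only merged when they share the same preferred alias.
        """
        alias = self.alias_a if side == "a" else self.alias_b
        uid = self.uid_a if side == "a" else self.uid_b
        for kind in preference:
            if kind == "alias" and alias:
                return alias
            if kind == "uid":
                return uid
        return uid


def _first_value(fld: str) -> str | None:
    """First ``db:value`` entry of a pipe-separated MITAB field, value part."""
    fld = fld.strip()
    if not fld or fld == "-":
        return None
    first = fld.split("|", 1)[0]
    value = first.split(":", 1)[1] if ":" in first else first
    value = value.strip('"')
    # strip trailing "(description)" decorations
    if "(" in value:
        value = value.split("(", 1)[0]
    return value or None


def _parse_taxid(fld: str) -> int | None:
    """``taxid:9606(Homo sapiens)`` -> 9606; ``-`` -> None; bare ints ok."""
    fld = fld.strip()
    if not fld or fld == "-":
        return None
    m = _TAXID_RE.search(fld)
    if m:
        return int(m.group(1))
    try:
        return int(fld)
    except ValueError:
        return None


def _parse_method(fld: str) -> str | None:
    """``psi-mi:"MI:0018"(two hybrid)`` -> ``MI:0018``; ``-`` -> None."""
    m = _MI_CODE_RE.search(fld)
    return m.group(0) if m else None


def parse_mitab(
    path: str | Path, dialect: MitabDialect | None = None
) -> list[InteractionRecord]:
    """Parse a MITAB file into interaction records.

    Comment lines (starting ``"#"``) and blank lines are skipped.  A data
    line with fewer columns than the dialect requires is skipped with a
    logged warning, never silently.

    Raises
    ------
    MitabError
        If the file cannot be read or yields no identifiers on a data line.
    """
    dialect = dialect or MitabDialect()
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise MitabError(f"cannot read MITAB file {path}: {exc}") from exc

    records: list[InteractionRecord] = []
    header_pending = dialect.skip_header
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        if header_pending:
            header_pending = False
            continue
        cols = line.split("\t")
        if len(cols) < dialect.min_columns:
            logger.warning(
                "MITAB %s line %d: %d columns, need %d -- record skipped",
                path.name,
                lineno,
                len(cols),
                dialect.min_columns,
            )
            continue
        uid_a = _first_value(cols[dialect.col_uid_a])
        uid_b = _first_value(cols[dialect.col_uid_b])
        if not uid_a or not uid_b:
            logger.warning(
                "MITAB %s line %d: empty interactor uid -- record skipped",
                path.name,
                lineno,
            )
            continue
        alias_a = _first_value(cols[dialect.col_alias_a]) or _first_value(
            cols[dialect.col_alt_a]
        )
        alias_b = _first_value(cols[dialect.col_alias_b]) or _first_value(
            cols[dialect.col_alt_b]
        )
        records.append(
            InteractionRecord(
                uid_a=uid_a,
                uid_b=uid_b,
                alias_a=alias_a,
                alias_b=alias_b,
                taxid_a=_parse_taxid(cols[dialect.col_taxid_a]),
                taxid_b=_parse_taxid(cols[dialect.col_taxid_b]),
                detection_method=_parse_method(cols[dialect.col_method]),
                source_line=lineno,
            )
        )
    return records


@dataclass(frozen=True)
class CurationPolicy:
    """Filters applied to raw interaction records.

    ``required_taxid`` keeps only records whose interactors are that taxon
    (default 9606, human).  With ``require_both_taxa_match`` both taxa must
    match and unknown taxa drop the record — the strictest reading of
    "non-human interactions were removed".  ``predicted_method_codes`` are
    PSI-MI detection-method codes treated as computational predictions; an
    empty set disables that filter.
    """

    required_taxid: int = 9606
    predicted_method_codes: frozenset[str] = DEFAULT_PREDICTED_CODES
    drop_self_loops: bool = True
    require_both_taxa_match: bool = True


@dataclass
class CurationReport:
    """Counts in/out per curation filter, in application order."""

    n_input: int = 0
    n_dropped_taxon: int = 0
    n_dropped_predicted: int = 0
    n_dropped_self: int = 0
    n_output: int = 0

    def log(self) -> None:
        logger.info(
            "curation: %d records in; dropped %d by taxon, %d predicted, "
            "%d self-interactions; %d records out",
            self.n_input,
            self.n_dropped_taxon,
            self.n_dropped_predicted,
            self.n_dropped_self,
            self.n_output,
        )


def _taxon_ok(rec: InteractionRecord, policy: CurationPolicy) -> bool:
    if policy.require_both_taxa_match:
        return (
            rec.taxid_a == policy.required_taxid
            and rec.taxid_b == policy.required_taxid
        )
    # lenient mode: a known mismatching taxon on either side drops the record
    for tax in (rec.taxid_a, rec.taxid_b):
        if tax is not None and tax != policy.required_taxid:
            return False
    return True


def curate_with_report(
    records: Iterable[InteractionRecord], policy: CurationPolicy | None = None
) -> tuple[list[InteractionRecord], CurationReport]:
    """Apply the curation filters, returning survivors and a count report.

    Filters only ever shrink the input; the operation is idempotent.
    """
    policy = policy or CurationPolicy()
    report = CurationReport()
    kept: list[InteractionRecord] = []
    for rec in records:
        report.n_input += 1
        if not _taxon_ok(rec, policy):
            report.n_dropped_taxon += 1
            continue
        if (
            rec.detection_method is not None
            and rec.detection_method in policy.predicted_method_codes
        ):
            report.n_dropped_predicted += 1
            continue
        if policy.drop_self_loops and rec.uid_a == rec.uid_b:
            report.n_dropped_self += 1
            continue
        kept.append(rec)
    report.n_output = len(kept)
    report.log()
    return kept, report


def curate(
    records: Iterable[InteractionRecord], policy: CurationPolicy | None = None
) -> list[InteractionRecord]:
    """Like :func:`curate_with_report` but returning only the survivors."""
    kept, _ = curate_with_report(records, policy)
    return kept


def build_graph(
    records: Iterable[InteractionRecord],
    label: str,
    id_preference: Sequence[str] = ("alias", "uid"),
) -> ProteinNetwork:
    """Convert curated records to a simple undirected network.

    Nodes are the resolved identifiers of every record; ``(a, b)`` and
    ``(b, a)`` collapse to one edge and multiplicity is discarded.  A record
    whose two interactors resolve to the same identifier contributes the
    node but no edge (the network stays loop-free regardless of policy).
    """
    records = list(records)
    if not records:
        logger.warning("build_graph(%r): no records, empty network", label)
    pairs = (
        (rec.identifier("a", id_preference), rec.identifier("b", id_preference))
        for rec in records
    )
    return ProteinNetwork.from_edges(label, pairs)
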