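"""Retroelement-insertion (RI) presence/absence matrices.

An RI matrix codes, for each taxon and each insertion locus, whether the
retroelement is present (1), absent (0) or unknown (?).  Each character
can be reduced to a single unrooted "bipartition gene tree": one internal
edge separating the present-coded from the absent-coded taxa, with
missing-coded taxa dropped.  Characters whose two sides both contain at
least ``min_side`` taxa are quartet-informative (with ``min_side=2`` they
induce at least one quartet and can contribute to quartet-based
species-tree inference).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import dendropy

PRESENT = 1
ABSENT = 0
MISSING = -1

_SYMBOL = {"1": PRESENT, "0": ABSENT, "?": MISSING}
_TO_SYMBOL = {PRESENT: "1", ABSENT: "0", MISSING: "?"}


class RIMatrixError(ValueError):
    """Malformed or inconsistent RI matrix input."""


@dataclass(frozen=True)
class TaxonSet:
    """Ordered, unique taxon labels; the order is stable across every
    structure derived from a matrix."""

    labels: Tuple[str, ...]

    def __post_init__(self):
        if len(set(self.labels)) != len(self.labels):
            dup = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise RIMatrixError("duplicate taxon label(s): %s" % ", ".join(dup))

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)


@dataclass
class RIMatrix:
    """taxa x loci table of {present, absent, missing} states.

    ``states`` is an int8 array with 1/0/-1; ``locus_ids`` default to
    1-based column indices.
    """

    taxa: TaxonSet
    states: np.ndarray
    locus_ids: List[Union[int, str]] = field(default_factory=list)

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.ndim != 2 or self.states.shape[0] != len(self.taxa):
            raise RIMatrixError("states must be a taxa x loci table")
        bad = ~np.isin(self.states, [PRESENT, ABSENT, MISSING])
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise RIMatrixError(
                "invalid state %r at taxon %s, locus column %d"
                % (self.states[i, j], self.taxa.labels[i], j + 1))
        if not self.locus_ids:
            self.locus_ids = list(range(1, self.states.shape[1] + 1))
        if len(self.locus_ids) != self.states.shape[1]:
            raise RIMatrixError("locus_ids length does not match column count")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_loci(self) -> int:
        return self.states.shape[1]

    def column(self, locus_id) -> np.ndarray:
        return self.states[:, self.locus_ids.index(locus_id)]

    def subset_loci(self, locus_ids: Sequence) -> "RIMatrix":
        idx = [self.locus_ids.index(l) for l in locus_ids]
        return RIMatrix(self.taxa, self.states[:, idx], list(locus_ids))

    def drop_loci(self, locus_ids: Sequence) -> "RIMatrix":
        drop = set(locus_ids)
        keep = [l for l in self.locus_ids if l not in drop]
        return self.subset_loci(keep)

    def to_frame(self) -> pd.DataFrame:
        sym = np.vectorize(_TO_SYMBOL.get)(self.states)
        return pd.DataFrame(sym, index=list(self.taxa.labels),
                            columns=self.locus_ids)


@dataclass(frozen=True)
class RIBipartition:
    """One character as a two-sided taxon split; missing-coded taxa are
    excluded entirely."""

    locus_id: Union[int, str]
    side_present: frozenset
    side_absent: frozenset
    excluded: frozenset

    def __post_init__(self):
        if not self.side_present or not self.side_absent:
            raise RIMatrixError(
                "bipartition %r has an empty side" % (self.locus_id,))
        if self.side_present & self.side_absent:
            raise RIMatrixError("sides overlap for locus %r" % (self.locus_id,))

    @property
    def leaf_set(self) -> frozenset:
        return self.side_present | self.side_absent


@dataclass
class MissingSummary:
    """Per-taxon missing-entry counts plus their grand mean."""

    per_taxon: pd.Series
    n_loci: int

    @property
    def mean(self) -> float:
        return float(self.per_taxon.mean())

    @property
    def fraction(self) -> float:
        return self.mean / self.n_loci if self.n_loci else 0.0

    @property
    def total(self) -> int:
        return int(self.per_taxon.sum())


# ---------------------------------------------------------------------------
# reading / writing


def _parse_tsv(text: str) -> Tuple[List[str], List[List[str]]]:
    rows = []
    for raw in text.splitlines():
        line = raw.rstrip("\n\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) == 1:
            fields = line.split()
        rows.append(fields)
    if not rows:
        raise RIMatrixError("empty TSV input")
    # header row: any entry past column 0 outside the state alphabet
    def is_states(fields: List[str]) -> bool:
        return all(all(ch in _SYMBOL for ch in f) for f in fields[1:]) \
            and len(fields) > 1
    if not is_states(rows[0]):
        rows = rows[1:]
        if not rows:
            raise RIMatrixError("TSV contains only a header row")
    labels, chars = [], []
    for r, fields in enumerate(rows):
        labels.append(fields[0])
        symbols: List[str] = []
        for f in fields[1:]:
            symbols.extend(f)          # allow "101?" packed in one field
        for c, s in enumerate(symbols):
            if s not in _SYMBOL:
                raise RIMatrixError(
                    "unknown state symbol %r at taxon %s, character %d"
                    % (s, fields[0], c + 1))
        chars.append(symbols)
    ncols = {len(c) for c in chars}
    if len(ncols) != 1:
        raise RIMatrixError("rows have differing character counts: %s"
                            % sorted(ncols))
    return labels, chars


def read_ri_matrix(path_or_text: str, format: Optional[str] = None) -> RIMatrix:
    """Read an RI matrix from NEXUS (datatype=standard, symbols 01,
    missing ?) or TSV (first column taxon label, one state per column;
    optional header row).

    ``format`` is ``"nexus"``/``"nexus-standard"``, ``"tsv"`` or None
    (inferred from the file extension / content).
    """
    if os.path.exists(path_or_text):
        with open(path_or_text) as fh:
            text = fh.read()
        if format is None:
            ext = os.path.splitext(path_or_text)[1].lower()
            format = "nexus" if ext in (".nex", ".nexus", ".nxs") else None
    else:
        text = path_or_text
    if format is None:
        format = "nexus" if text.lstrip().lower().startswith("#nexus") else "tsv"
    format = {"nexus-standard": "nexus"}.get(format, format)

    if format == "nexus":
        try:
            cm = dendropy.StandardCharacterMatrix.get(
                data=text, schema="nexus")
        except Exception as exc:
            raise RIMatrixError("cannot parse NEXUS matrix: %s" % exc) from exc
        labels, chars = [], []
        for taxon in cm.taxon_namespace:
            labels.append(taxon.label)
            symbols = [str(ch.symbol) for ch in cm[taxon]]
            for c, s in enumerate(symbols):
                if s not in _SYMBOL:
                    raise RIMatrixError(
                        "unknown state symbol %r at taxon %s, character %d"
                        % (s, taxon.label, c + 1))
            chars.append(symbols)
    elif format == "tsv":
        labels, chars = _parse_tsv(text)
    else:
        raise RIMatrixError("unknown format %r" % format)

    states = np.array([[_SYMBOL[s] for s in row] for row in chars],
                      dtype=np.int8)
    return RIMatrix(TaxonSet(tuple(labels)), states)


def write_ri_matrix(m: RIMatrix, path: str, format: str = "tsv") -> None:
    """Write a matrix back out (TSV or NEXUS standard); round-trips
    states exactly."""
    format = {"nexus-standard": "nexus"}.get(format, format)
    if format == "tsv":
        with open(path, "w") as fh:
            for i, lab in enumerate(m.taxa):
                syms = "".join(_TO_SYMBOL[int(s)] for s in m.states[i])
                fh.write("%s\t%s\n" % (lab, "\t".join(syms)))
    elif format == "nexus":
        buf = io.StringIO()
        buf.write("#NEXUS\nBEGIN DATA;\n")
        buf.write("  DIMENSIONS NTAX=%d NCHAR=%d;\n" % (m.n_taxa, m.n_loci))
        buf.write('  FORMAT DATATYPE=STANDARD SYMBOLS="01" MISSING=?;\n')
        buf.write("  MATRIX\n")
        width = max(len(l) for l in m.taxa.labels)
        for i, lab in enumerate(m.taxa):
            syms = "".join(_TO_SYMBOL[int(s)] for s in m.states[i])
            buf.write("    %-*s %s\n" % (width, _nexus_label(lab), syms))
        buf.write("  ;\nEND;\n")
        with open(path, "w") as fh:
            fh.write(buf.getvalue())
    else:
        raise RIMatrixError("unknown format %r" % format)


def _nexus_label(label: str) -> str:
    if any(ch.isspace() or ch in "()[]{}/\\,;:=*'\"`+<>" for ch in label):
        return "'%s'" % label.replace("'", "''")
    return label


# ---------------------------------------------------------------------------
# conversion and summaries


def to_bipartitions(m: RIMatrix, min_side: int = 1,
                    return_dropped: bool = False):
    """One RIBipartition per character whose present and absent sides each
    hold at least ``min_side`` taxa.

    ``min_side=2`` keeps exactly the quartet-informative characters (a
    2+2 split is the minimal configuration inducing any quartet).  With
    ``return_dropped=True`` the ids of filtered characters are returned as
    a second value.
    """
    if min_side < 1:
        raise RIMatrixError("min_side must be >= 1")
    labels = np.array(m.taxa.labels)
    bps: List[RIBipartition] = []
    dropped: List = []
    for j, locus_id in enumerate(m.locus_ids):
        col = m.states[:, j]
        pres = frozenset(labels[col == PRESENT])
        absn = frozenset(labels[col == ABSENT])
        if len(pres) >= min_side and len(absn) >= min_side:
            bps.append(RIBipartition(
                locus_id=locus_id, side_present=pres, side_absent=absn,
                excluded=frozenset(labels[col == MISSING])))
        else:
            dropped.append(locus_id)
    if return_dropped:
        return bps, dropped
    return bps


def bipartition_to_column(bp: RIBipartition, taxa: TaxonSet) -> np.ndarray:
    """Reconstruct a character column from a bipartition (excluded taxa
    come back as missing)."""
    col = np.full(len(taxa), MISSING, dtype=np.int8)
    for i, lab in enumerate(taxa):
        if lab in bp.side_present:
            col[i] = PRESENT
        elif lab in bp.side_absent:
            col[i] = ABSENT
    return col


def missing_summary(m: RIMatrix) -> MissingSummary:
    counts = (m.states == MISSING).sum(axis=1)
    per_taxon = pd.Series(counts, index=list(m.taxa.labels), name="missing")
    return MissingSummary(per_taxon=per_taxon, n_loci=m.n_loci)


def write_bipartition_newick(bps: Sequence[RIBipartition], path: str) -> None:
    """One newick line per bipartition: a single internal edge separating
    the present side from the absent side; excluded taxa are omitted."""
    if not bps:
        raise RIMatrixError("no bipartitions to write")
    with open(path, "w") as fh:
        for bp in bps:
            fh.write(bipartition_newick(bp) + "\n")


def bipartition_newick(bp: RIBipartition) -> str:
    left = ",".join(sorted(bp.side_present))
    right = ",".join(sorted(bp.side_absent))
    if len(bp.side_present) == 1:
        left_s = left
    else:
        left_s = "(%s)" % left
    if len(bp.side_absent) == 1:
        right_s = right
    else:
        right_s = "(%s)" % right
    return "(%s,%s);" % (left_s, right_s)
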