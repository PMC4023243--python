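"""Barcoding-distance analysis on aligned sequences.

Pairwise distances are computed with pairwise deletion (columns where either
sequence has a gap or an ambiguity are dropped for that pair).  The GTR
distance uses the closed-form divergence-matrix estimator

    d = -tr( Pi * log( Pi^-1 * Fhat ) )

where Fhat is the symmetrized matrix of observed pattern proportions and Pi
the diagonal matrix of the averaged base frequencies of the pair.  Identical
sequences give 0; saturated pairs (log undefined) are flagged NaN.

Indel coding follows simple indel coding: every maximal internal gap run
with identical start and end columns across the taxa that share it becomes
one binary presence/absence character, regardless of indel length.  Terminal
overhangs are excluded, and taxa whose sequence is entirely gapped across a
character's span are scored as missing.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedSeqSet",
    "DistanceMatrix",
    "IndelCharacter",
    "IndelCharacterSet",
    "read_alignment",
    "write_alignment",
    "read_otu_map",
    "gtr_distance",
    "p_distance",
    "distance_matrix",
    "barcoding_gap_summary",
    "code_indels",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
GAP = "-"


class AlignmentError(ValueError):
    """Raised on malformed alignments or sequence sets."""


@dataclass(frozen=True)
class AlignedSeqSet:
    """Equal-length aligned sequences with OTU labels."""

    ids: tuple[str, ...]
    otus: tuple[str, ...]
    seqs: tuple[str, ...] = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs) or len(self.ids) != len(self.otus):
            raise AlignmentError("ids, otus and seqs must share one length")
        if len(set(self.ids)) != len(self.ids):
            raise AlignmentError("duplicate sequence ids")
        lengths = {len(s) for s in self.seqs}
        if len(lengths) > 1:
            raise AlignmentError(f"ragged alignment: lengths {sorted(lengths)}")
        for sid, s in zip(self.ids, self.seqs):
            if not any(c in _BASE_INDEX for c in s):
                raise AlignmentError(f"{sid}: no unambiguous base")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def encoded(self) -> np.ndarray:
        """(n, length) int8 matrix: 0..3 = ACGT, -1 = gap/ambiguity."""
        out = np.full((self.n, self.length), -1, dtype=np.int8)
        for i, s in enumerate(self.seqs):
            arr = np.frombuffer(s.encode(), dtype=np.uint8)
            for b, code in _BASE_INDEX.items():
                out[i, arr == ord(b)] = code
        return out

    def by_otu(self, *otus: str) -> "AlignedSeqSet":
        keep = [i for i, o in enumerate(self.otus) if o in otus]
        return AlignedSeqSet(
            tuple(self.ids[i] for i in keep),
            tuple(self.otus[i] for i in keep),
            tuple(self.seqs[i] for i in keep),
        )


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_otu_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sequence_id, otu) -> dict."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise AlignmentError(f"{path}:{lineno}: expected 2 tab-separated "
                                 "columns")
        out[parts[0].strip()] = parts[1].strip()
    return out


def read_alignment(
    source: str | Path | io.TextIOBase,
    otu_map: dict[str, str] | None = None,
) -> AlignedSeqSet:
    """Read an aligned FASTA; attach OTU labels.

    Labels come from ``otu_map`` when given, else from the second
    whitespace-separated header token, else the id itself.  Sequences are
    uppercased and U is normalized to T.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    if not text.strip():
        raise AlignmentError("empty FASTA input")
    handle = io.StringIO(text)
    ids, otus, seqs = [], [], []
    for rec in SeqIO.parse(handle, "fasta"):
        ids.append(rec.id)
        tokens = rec.description.split()
        if otu_map is not None:
            if rec.id not in otu_map:
                raise AlignmentError(f"{rec.id}: missing from OTU map")
            otus.append(otu_map[rec.id])
        elif len(tokens) > 1:
            otus.append(tokens[1])
        else:
            otus.append(rec.id)
        seqs.append(_normalize(str(rec.seq)))
    if not ids:
        raise AlignmentError("no FASTA records parsed")
    return AlignedSeqSet(tuple(ids), tuple(otus), tuple(seqs))


def write_alignment(aln: AlignedSeqSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=i, description=o)
        for i, o, s in zip(aln.ids, aln.otus, aln.seqs)
    ]
    SeqIO.write(records, str(path), "fasta")


# ----------------------------------------------------------------------
# distances

def _pair_arrays(seq_a: str | np.ndarray, seq_b: str | np.ndarray):
    if isinstance(seq_a, str):
        seq_a = AlignedSeqSet(("a",), ("a",), (_normalize(seq_a),)).encoded()[0]
    if isinstance(seq_b, str):
        seq_b = AlignedSeqSet(("b",), ("b",), (_normalize(seq_b),)).encoded()[0]
    if len(seq_a) != len(seq_b):
        raise AlignmentError("sequences differ in aligned length")
    mask = (seq_a >= 0) & (seq_b >= 0)
    return seq_a[mask], seq_b[mask]


def p_distance(seq_a, seq_b) -> float:
    """Proportion of differing sites under pairwise deletion."""
    a, b = _pair_arrays(seq_a, seq_b)
    if len(a) == 0:
        raise AlignmentError("no usable (unambiguous) columns in common")
    return float(np.mean(a != b))


def gtr_distance(seq_a, seq_b, min_sites: int = 50) -> float:
    """Closed-form GTR distance (substitutions/site), pairwise deletion.

    Returns NaN when the estimator is undefined (saturation: the
    symmetrized divergence matrix has a nonpositive eigenvalue after
    frequency scaling).  Fewer than ``min_sites`` usable sites logs a
    warning.
    """
    a, b = _pair_arrays(seq_a, seq_b)
    n = len(a)
    if n == 0:
        raise AlignmentError("no usable (unambiguous) columns in common")
    if n < min_sites:
        logger.warning("only %d usable sites for a pair (min %d)", n, min_sites)
    if np.array_equal(a, b):
        return 0.0
    f = np.zeros((4, 4))
    np.add.at(f, (a, b), 1.0)
    f /= n
    fhat = (f + f.T) / 2.0
    pi = fhat.sum(axis=1)  # averaged empirical base frequencies of the pair
    present = pi > 0
    fhat = fhat[np.ix_(present, present)]
    pi = pi[present]
    inv_sqrt = 1.0 / np.sqrt(pi)
    s = fhat * np.outer(inv_sqrt, inv_sqrt)
    evals, evecs = np.linalg.eigh((s + s.T) / 2.0)
    if np.any(evals <= 0):
        logger.warning("saturated pair: GTR distance undefined")
        return float("nan")
    # d = -tr(Pi log(Pi^-1 Fhat)) = -sum_k log(l_k) * sum_i pi_i V_ik^2
    weights = (pi[:, None] * evecs**2).sum(axis=0)
    return float(-(np.log(evals) * weights).sum())


def _pair_distance(a, b, model: str) -> float:
    if model == "gtr":
        return gtr_distance(a, b)
    if model == "p":
        return p_distance(a, b)
    raise ValueError(f"unknown model {model!r}")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with OTU-tagged labels."""

    ids: tuple[str, ...]
    otus: tuple[str, ...]
    d: np.ndarray = field(repr=False)
    model: str = "gtr"
    sites_used: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise AlignmentError("distance matrix shape mismatch")
        if not np.allclose(self.d, self.d.T, atol=1e-12, equal_nan=True):
            raise AlignmentError("distance matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise AlignmentError("nonzero diagonal")
        with np.errstate(invalid="ignore"):
            if np.any(self.d < 0):
                raise AlignmentError("negative distance")

    def to_frame(self, percent: bool = False) -> pd.DataFrame:
        vals = self.d * 100.0 if percent else self.d
        return pd.DataFrame(vals, index=list(self.ids), columns=list(self.ids))

    def to_phylip(self) -> str:
        lines = [str(len(self.ids))]
        for i, sid in enumerate(self.ids):
            row = " ".join(f"{x:.8f}" for x in self.d[i])
            lines.append(f"{sid:<12s}{row}")
        return "\n".join(lines) + "\n"


def distance_matrix(aln: AlignedSeqSet, model: str = "gtr") -> DistanceMatrix:
    """All-pairs distance matrix under the chosen model."""
    if aln.n < 2:
        raise AlignmentError("need at least 2 sequences")
    enc = aln.encoded()
    n = aln.n
    d = np.zeros((n, n))
    sites = np.zeros((n, n), dtype=int)
    usable = enc >= 0
    for i in range(n):
        sites[i, i] = int(usable[i].sum())
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = _pair_distance(enc[i], enc[j], model)
            sites[i, j] = sites[j, i] = int((usable[i] & usable[j]).sum())
    return DistanceMatrix(aln.ids, aln.otus, d, model=model, sites_used=sites)


def barcoding_gap_summary(dm: DistanceMatrix) -> pd.DataFrame:
    """Within/between-OTU distance summary (the barcoding-gap table).

    One row per OTU: n, maximum within-OTU distance (NaN for singletons,
    flagged), nearest other OTU with the minimum and maximum between
    distances to it, and a gap flag set when within-max < between-min.
    Distances are reported in percent.
    """
    otus = sorted(set(dm.otus))
    if len(otus) < 2:
        raise AlignmentError("need at least 2 OTUs for a gap summary")
    labels = np.asarray(dm.otus)
    rows = []
    for otu in otus:
        idx = np.where(labels == otu)[0]
        within = dm.d[np.ix_(idx, idx)]
        if len(idx) > 1:
            iu = np.triu_indices(len(idx), k=1)
            wmax = float(np.nanmax(within[iu]))
        else:
            wmax = float("nan")
        best = None
        for other in otus:
            if other == otu:
                continue
            jdx = np.where(labels == other)[0]
            block = dm.d[np.ix_(idx, jdx)]
            bmin = float(np.nanmin(block))
            bmax = float(np.nanmax(block))
            if best is None or bmin < best[1]:
                best = (other, bmin, bmax)
        nearest, bmin, bmax = best
        # singleton OTUs contribute no within spread: treat within-max as 0
        gap = bool((0.0 if np.isnan(wmax) else wmax) < bmin)
        rows.append(
            {
                "otu": otu,
                "n": len(idx),
                "within_max_pct": wmax * 100.0,
                "nearest_otu": nearest,
                "between_min_pct": bmin * 100.0,
                "between_max_pct": bmax * 100.0,
                "gap_flag": int(gap),
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# indel coding

@dataclass(frozen=True)
class IndelCharacter:
    """One simple-indel-coding character: a (start, end) gap run.

    ``states`` has one entry per taxon: 1 = indel present (exact run),
    0 = absent, -1 = missing (span inside a larger gap or a terminal
    overhang).  Columns are 0-based, end exclusive.
    """

    start: int
    end: int
    states: tuple[int, ...]

    @property
    def classification(self) -> str:
        counts = [self.states.count(0), self.states.count(1)]
        if min(counts) >= 2:
            return "parsimony-informative"
        if min(counts) == 1:
            return "autapomorphic"
        return "constant"


@dataclass(frozen=True)
class IndelCharacterSet:
    ids: tuple[str, ...]
    characters: tuple[IndelCharacter, ...]

    def counts(self) -> dict[str, int]:
        out = {"parsimony-informative": 0, "autapomorphic": 0, "constant": 0}
        for c in self.characters:
            out[c.classification] += 1
        out["total"] = len(self.characters)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "char": np.arange(1, len(self.characters) + 1),
                "start": [c.start + 1 for c in self.characters],  # 1-based
                "end": [c.end for c in self.characters],
                "class": [c.classification for c in self.characters],
            }
        )

    def to_phylip(self) -> str:
        """Relaxed-PHYLIP binary matrix; missing scored '?'."""
        sym = {0: "0", 1: "1", -1: "?"}
        lines = [f"{len(self.ids)} {len(self.characters)}"]
        for i, sid in enumerate(self.ids):
            row = "".join(sym[c.states[i]] for c in self.characters)
            lines.append(f"{sid:<12s}{row}")
        return "\n".join(lines) + "\n"


def _gap_runs(seq: str) -> list[tuple[int, int]]:
    return [(m.start(), m.end()) for m in re.finditer(r"-+", seq)]


def code_indels(aln: AlignedSeqSet) -> IndelCharacterSet:
    """Simple indel coding of an alignment.

    One insertion or deletion is one binary character regardless of its
    size: every distinct internal (start, end) gap run becomes a character.
    Gapless alignments yield an empty set.
    """
    length = aln.length
    runs_per_taxon: list[list[tuple[int, int]]] = []
    terminal: list[list[tuple[int, int]]] = []
    for s in aln.seqs:
        runs = _gap_runs(s)
        internal, term = [], []
        for start, end in runs:
            if start == 0 or end == length:
                term.append((start, end))
            else:
                internal.append((start, end))
        runs_per_taxon.append(internal)
        terminal.append(term)
    spans = sorted({r for runs in runs_per_taxon for r in runs})
    characters = []
    for start, end in spans:
        states = []
        for i in range(aln.n):
            if (start, end) in runs_per_taxon[i]:
                states.append(1)
            else:
                covering = [
                    r for r in runs_per_taxon[i] + terminal[i]
                    if r[0] <= start and end <= r[1]
                ]
                states.append(-1 if covering else 0)
        characters.append(IndelCharacter(start, end, tuple(states)))
    return IndelCharacterSet(aln.ids, tuple(characters))
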