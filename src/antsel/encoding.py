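"""Physicochemical sliding-window encoding of annotated protein sequences.

A candidate phosphorylation site (S/T/Y residue) is represented by the
window of flanking residues around it (default 21 residues, i.e. +/-10).
Each flanking residue maps to 10 min-max-normalized physicochemical
property values; the invariant center residue is dropped before encoding,
so a window of width W yields (W-1)*10 features (200 for the default).

The module reads multi-record FASTA via Biopython and a 4-column TSV of
site annotations (sequence_id, position, residue, label; positions are
1-based), and writes encoded datasets as TSV with a header of feature
names plus a ``label`` column.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
PAD = "X"
PHOSPHO_RESIDUES = ("S", "T", "Y")


# ---------------------------------------------------------------------------
# Property table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PropertyTable:
    """Normalized per-amino-acid physicochemical properties.

    ``values[aa]`` is a length-10 vector in [0, 1]; each property column is
    min-max normalized over the 20 standard amino acids. ``pad_vector`` is
    the per-property mean of the 20 normalized values, used for the 'X'
    padding symbol so that padding is information-neutral.
    """

    properties: tuple[str, ...]
    values: Mapping[str, np.ndarray]
    pad_vector: np.ndarray

    @property
    def n_properties(self) -> int:
        return len(self.properties)

    def vector(self, residue: str) -> np.ndarray:
        if residue == PAD:
            return self.pad_vector
        return self.values[residue]


def load_property_table(source: str | Path = "default") -> PropertyTable:
    """Load and min-max normalize a raw amino-acid property table.

    Parameters
    ----------
    source
        Path to a TSV (rows = amino acids, first column ``aa``; remaining
        columns = property names), or ``"default"`` for the bundled table
        of 10 properties (five factor-analytic scores covering polarity,
        secondary structure, molecular volume, codon diversity and
        electrostatic charge, plus hydrophobicity, side-chain length,
        helix propensity, codon number and strand propensity).

    Raises
    ------
    ValueError
        If an amino acid or property is missing, or a property column is
        constant (degenerate: cannot be min-max normalized).
    """
    if source == "default":
        ref = importlib.resources.files("antsel.data") / "property_table.tsv"
        with importlib.resources.as_file(ref) as p:
            raw = pd.read_csv(p, sep="\t", comment="#", index_col="aa")
    else:
        raw = pd.read_csv(source, sep="\t", comment="#", index_col="aa")

    missing_aa = sorted(set(STANDARD_AA) - set(raw.index))
    if missing_aa:
        raise ValueError(f"property table missing amino acids: {missing_aa}")
    extra = sorted(set(raw.index) - set(STANDARD_AA))
    if extra:
        raise ValueError(f"property table has non-standard rows: {extra}")
    if raw.shape[1] == 0:
        raise ValueError("property table has no property columns")

    raw = raw.loc[list(STANDARD_AA)].astype(float)
    if raw.isna().any().any():
        bad = sorted(raw.columns[raw.isna().any()])
        raise ValueError(f"property table has missing values in: {bad}")

    lo = raw.min(axis=0)
    hi = raw.max(axis=0)
    span = hi - lo
    degenerate = sorted(span.index[span == 0.0])
    if degenerate:
        raise ValueError(f"degenerate property (constant column): {degenerate}")
    norm = (raw - lo) / span

    values = {aa: norm.loc[aa].to_numpy(dtype=float) for aa in STANDARD_AA}
    pad = norm.mean(axis=0).to_numpy(dtype=float)
    return PropertyTable(
        properties=tuple(norm.columns), values=values, pad_vector=pad
    )


# ---------------------------------------------------------------------------
# Annotations and fragments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SiteAnnotation:
    """One candidate site: 1-based position of an S/T/Y in a sequence."""

    sequence_id: str
    position: int  # 1-based residue index
    residue: str
    label: str  # "positive" | "negative"


@dataclass(frozen=True)
class Fragment:
    """A fixed-width window of residues centered on a candidate site."""

    residues: str
    center_residue: str
    label: str
    origin: tuple[str, int]

    def __post_init__(self):
        w = len(self.residues)
        if w % 2 == 0:
            raise ValueError(f"fragment width must be odd, got {w}")
        center = self.residues[w // 2]
        if center not in (self.center_residue, PAD):
            raise ValueError(
                f"center residue {center!r} does not match {self.center_residue!r}"
            )

    @property
    def window(self) -> int:
        return len(self.residues)


@dataclass
class FragmentDataset:
    """Encoded fragments: X is (#fragments, (W-1)*10), values in [0, 1]."""

    fragments: list[Fragment]
    X: np.ndarray
    y: np.ndarray
    feature_names: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df["label"] = self.y
        return df

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_annotations(path: str | Path) -> list[SiteAnnotation]:
    """Read a 4-column annotation TSV (sequence_id, position, residue, label)."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"sequence_id": str, "position": int, "residue": str, "label": str},
    )
    required = {"sequence_id", "position", "residue", "label"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation file missing columns: {sorted(missing)}")
    return [
        SiteAnnotation(r.sequence_id, int(r.position), r.residue, r.label)
        for r in df.itertuples(index=False)
    ]


def write_annotations(annotations: Iterable[SiteAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [(a.sequence_id, a.position, a.residue, a.label) for a in annotations],
        columns=["sequence_id", "position", "residue", "label"],
    ).to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-record FASTA into an id -> uppercase sequence map."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def extract_fragments(
    sequences: Mapping[str, str],
    annotations: Iterable[SiteAnnotation],
    window: int = 21,
) -> list[Fragment]:
    """Excise a fixed-width fragment around each annotated site.

    Sites closer than (window-1)/2 to a sequence terminus are padded with
    'X'. An annotation whose stated residue does not match the sequence is
    a hard error naming every offending (sequence_id, position) pair.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    half = (window - 1) // 2

    mismatches = []
    fragments = []
    for ann in annotations:
        seq = sequences.get(ann.sequence_id)
        if seq is None:
            raise KeyError(f"annotation references unknown sequence {ann.sequence_id!r}")
        if not (1 <= ann.position <= len(seq)):
            raise ValueError(
                f"position {ann.position} out of range for {ann.sequence_id!r} "
                f"(length {len(seq)})"
            )
        actual = seq[ann.position - 1]
        if actual != ann.residue:
            mismatches.append((ann.sequence_id, ann.position, ann.residue, actual))
            continue
        start = ann.position - 1 - half
        stop = ann.position - 1 + half + 1
        left_pad = max(0, -start)
        right_pad = max(0, stop - len(seq))
        core = seq[max(0, start) : min(len(seq), stop)]
        residues = PAD * left_pad + core + PAD * right_pad
        fragments.append(
            Fragment(
                residues=residues,
                center_residue=ann.residue,
                label=ann.label,
                origin=(ann.sequence_id, ann.position),
            )
        )
    if mismatches:
        detail = ", ".join(
            f"({sid}, {pos}: annotated {want!r}, found {got!r})"
            for sid, pos, want, got in mismatches
        )
        raise ValueError(f"annotation/sequence residue mismatch: {detail}")
    return fragments


def mine_negative_annotations(
    sequences: Mapping[str, str],
    positive_annotations: Iterable[SiteAnnotation],
    residues: Iterable[str] = PHOSPHO_RESIDUES,
) -> list[SiteAnnotation]:
    """Enumerate candidate negative sites.

    Every S/T/Y occurrence (restricted to ``residues``, e.g. only 'S' for a
    serine-specific model) that is not in the positive annotation list
    becomes a candidate negative. Candidates are pooled across proteins.
    """
    wanted = set(residues)
    positive = {(a.sequence_id, a.position) for a in positive_annotations}
    negatives = []
    for sid in sorted(sequences):
        seq = sequences[sid]
        for i, aa in enumerate(seq, start=1):
            if aa in wanted and (sid, i) not in positive:
                negatives.append(SiteAnnotation(sid, i, aa, "negative"))
    return negatives


def balance_negatives(
    positives: list[Fragment],
    negatives: list[Fragment],
    ratio: float = 1.0,
    seed: int = 0,
) -> list[Fragment]:
    """Sample negatives without replacement to ``ratio`` times the positives.

    The default 1:1 ratio counters the heavy class imbalance of candidate
    sites (non-annotated S/T/Y outnumber annotated sites by an order of
    magnitude or more). Reproducible under ``seed``.
    """
    n_wanted = int(round(ratio * len(positives)))
    if n_wanted > len(negatives):
        raise ValueError(
            f"need {n_wanted} negatives (ratio {ratio} x {len(positives)} "
            f"positives) but only {len(negatives)} available"
        )
    if n_wanted == 0:
        return []
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(negatives), size=n_wanted, replace=False)
    return [negatives[i] for i in sorted(idx)]


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------

def feature_name(position: int, prop: str) -> str:
    return f"pos{position:+d}:{prop}"


def parse_feature_name(name: str) -> tuple[int, str]:
    """Inverse of :func:`feature_name`: 'pos-10:hydrophobicity' -> (-10, ...)."""
    pos_part, prop = name.split(":", 1)
    if not pos_part.startswith("pos"):
        raise ValueError(f"not a feature name: {name!r}")
    return int(pos_part[3:]), prop


def feature_position(name: str) -> int:
    return parse_feature_name(name)[0]


def encode(
    fragments: list[Fragment],
    table: PropertyTable | None = None,
    on_nonstandard: str = "error",
) -> FragmentDataset:
    """Encode fragments into a (#fragments, (W-1)*n_properties) matrix.

    The center residue is invariant by construction (always the model's
    S/T/Y) and is dropped. Remaining residues are laid out position-major
    (pos -(W-1)/2 ... -1, +1 ... +(W-1)/2), property-minor; 'X' maps to the
    table's pad vector. Non-standard residues other than 'X' raise by
    default (``on_nonstandard="pad"`` maps them to the pad vector instead).
    """
    if table is None:
        table = load_property_table()
    if not fragments:
        raise ValueError("no fragments to encode")
    window = fragments[0].window
    if any(f.window != window for f in fragments):
        raise ValueError("fragments do not share a common window width")
    if on_nonstandard not in ("error", "pad"):
        raise ValueError(f"on_nonstandard must be 'error' or 'pad': {on_nonstandard!r}")

    half = (window - 1) // 2
    positions = [p for p in range(-half, half + 1) if p != 0]
    names = [feature_name(p, prop) for p in positions for prop in table.properties]

    nprop = table.n_properties
    X = np.empty((len(fragments), len(positions) * nprop), dtype=float)
    for r, frag in enumerate(fragments):
        for c, pos in enumerate(positions):
            aa = frag.residues[half + pos]
            if aa in table.values:
                vec = table.values[aa]
            elif aa == PAD or on_nonstandard == "pad":
                vec = table.pad_vector
            else:
                raise ValueError(
                    f"non-standard residue {aa!r} at {frag.origin} "
                    f"(position {pos:+d}); pass on_nonstandard='pad' to encode it"
                )
            X[r, c * nprop : (c + 1) * nprop] = vec
    y = np.array([1 if f.label == "positive" else 0 for f in fragments], dtype=int)
    return FragmentDataset(fragments=list(fragments), X=X, y=y, feature_names=names)


def read_dataset_tsv(path: str | Path) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Read an encoded dataset TSV back into (X, y, feature_names)."""
    df = pd.read_csv(path, sep="\t")
    if "label" not in df.columns:
        raise ValueError("dataset TSV lacks a 'label' column")
    y = df.pop("label").to_numpy(dtype=int)
    return df.to_numpy(dtype=float), y, list(df.columns)


# ---------------------------------------------------------------------------
# Redundancy filter
# ---------------------------------------------------------------------------

def _identity(a: str, b: str) -> float:
    """Ungapped pairwise identity: matches over the shorter length.

    Sequences are compared position-by-position from their N-termini; the
    denominator is the shorter sequence length. This is a deliberately
    simple surrogate for clustering-based redundancy removal, adequate for
    the near-duplicate case it is meant to catch.
    """
    n = min(len(a), len(b))
    if n == 0:
        return 0.0
    matches = sum(1 for x, y in zip(a[:n], b[:n]) if x == y)
    return matches / n


def _kmer_set(seq: str, k: int = 5) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def redundancy_filter(
    sequences: Mapping[str, str], threshold: float = 0.7
) -> dict[str, str]:
    """Greedy longest-first redundancy removal on pairwise identity.

    Retains a subset such that no retained pair has identity >= threshold.
    A shared-k-mer screen skips the exact comparison for pairs with no
    5-mer in common (such pairs cannot reach any practical threshold).
    Off the main pipeline by default; sequence sets already filtered
    externally (e.g. with a clustering tool) can skip this.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    order = sorted(sequences, key=lambda sid: (-len(sequences[sid]), sid))
    kept: list[str] = []
    kmers: dict[str, set[str]] = {}
    for sid in order:
        seq = sequences[sid]
        sk = _kmer_set(seq)
        redundant = False
        for other in kept:
            if sk and kmers[other] and not (sk & kmers[other]):
                continue
            if _identity(seq, sequences[other]) >= threshold:
                redundant = True
                break
        if not redundant:
            kept.append(sid)
            kmers[sid] = sk
    return {sid: sequences[sid] for sid in sorted(kept)}
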