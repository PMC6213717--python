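"""Reading and writing sequences, per-residue score tables, and predictions.

The on-disk formats are deliberately plain: FASTA for sequences and
tab-separated tables for per-residue component-predictor scores, labels and
predictions.  The in-memory representation groups score rows per sequence
into :class:`ScoreProfile` objects collected in a :class:`Dataset`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

#: Fixed order of the four component-predictor score channels.  The letters
#: follow the predictors whose roles the channels play: DisEMBL (D),
#: IUPred (I), VSL2 (V) and ESpritz (E).  Channel order is preserved through
#: every pipeline stage.
CHANNELS = ("D", "I", "V", "E")

_VALID_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_SCORE_COLUMNS = ["score_D", "score_I", "score_V", "score_E"]
_BASE_COLUMNS = ["seq_id", "position", "residue"] + _SCORE_COLUMNS


class FormatError(ValueError):
    """Raised when an input file violates the expected format."""


@dataclass
class SequenceRecord:
    """One protein sequence.

    Parameters
    ----------
    seq_id : str
        Identifier (the FASTA header token before the first whitespace).
    residues : str
        One-letter amino-acid codes; the 20 standard codes plus ``X``.
    """

    seq_id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise FormatError(f"sequence {self.seq_id!r} is empty")
        bad = set(self.residues.upper()) - _VALID_RESIDUES
        if bad:
            raise FormatError(
                f"sequence {self.seq_id!r} contains non-residue characters "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ScoreProfile:
    """Per-residue component-predictor scores for one sequence.

    ``scores`` has shape ``(L, 4)`` with one column per channel in
    :data:`CHANNELS` order.  ``labels`` is ``None`` in prediction mode,
    otherwise an ``(L,)`` array with 1 = disordered, 0 = structured.
    Positions are 1-based and contiguous; terminal distances are derived
    from position and ``L``.
    """

    seq_id: str
    residues: str
    scores: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != len(CHANNELS):
            raise FormatError(
                f"{self.seq_id!r}: scores must be (L, {len(CHANNELS)}), "
                f"got {self.scores.shape}"
            )
        if self.scores.shape[0] != len(self.residues):
            raise FormatError(
                f"{self.seq_id!r}: {self.scores.shape[0]} score rows for "
                f"{len(self.residues)} residues"
            )
        if not np.all(np.isfinite(self.scores)):
            raise FormatError(f"{self.seq_id!r}: non-finite score")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if self.labels.shape != (len(self.residues),):
                raise FormatError(f"{self.seq_id!r}: label/residue length mismatch")
            if not np.isin(self.labels, (0, 1)).all():
                raise FormatError(f"{self.seq_id!r}: labels must be 0 or 1")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def positions(self) -> np.ndarray:
        """1-based residue positions ``1..L``."""
        return np.arange(1, len(self) + 1)

    @property
    def n_terminal_distance(self) -> np.ndarray:
        """Distance from the N terminus (first residue = 1)."""
        return self.positions

    @property
    def c_terminal_distance(self) -> np.ndarray:
        """Distance from the C terminus (last residue = 1)."""
        return len(self) - self.positions + 1


@dataclass
class Dataset:
    """A collection of :class:`ScoreProfile` with fixed channel order."""

    profiles: list[ScoreProfile]
    channel_names: tuple[str, ...] = CHANNELS
    provenance: str = ""
    _index: dict = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {p.seq_id: p for p in self.profiles}
        if len(self._index) != len(self.profiles):
            raise FormatError("duplicate seq_id in dataset")

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self):
        return iter(self.profiles)

    def __getitem__(self, seq_id: str) -> ScoreProfile:
        return self._index[seq_id]

    @property
    def is_labelled(self) -> bool:
        return bool(self.profiles) and all(p.labels is not None for p in self.profiles)

    @property
    def n_residues(self) -> int:
        return sum(len(p) for p in self.profiles)

    def subset(self, seq_ids) -> "Dataset":
        """New dataset restricted to ``seq_ids``, preserving file order."""
        wanted = set(seq_ids)
        return Dataset(
            [p for p in self.profiles if p.seq_id in wanted],
            self.channel_names,
            self.provenance,
        )

    def stacked(self, mask_fn=None) -> tuple[np.ndarray, np.ndarray | None]:
        """Stack scores (and labels when present) across profiles.

        ``mask_fn(profile) -> bool array`` optionally selects residues.
        """
        xs, ys = [], []
        for p in self.profiles:
            m = np.ones(len(p), bool) if mask_fn is None else mask_fn(p)
            xs.append(p.scores[m])
            if p.labels is not None:
                ys.append(p.labels[m])
        X = np.vstack(xs) if xs else np.empty((0, len(CHANNELS)))
        y = np.concatenate(ys) if ys and len(ys) == len(xs) else None
        return X, y


def read_fasta(path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    The header token before the first whitespace becomes ``seq_id``.
    Duplicate identifiers and non-residue characters are format errors.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq).upper()))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def read_score_table(path) -> Dataset:
    """Read a tab-separated per-residue score table into a :class:`Dataset`.

    Expected columns: ``seq_id  position  residue  score_D  score_I
    score_V  score_E  [label]``.  Rows are grouped by ``seq_id``;
    positions must be 1-based and contiguous within each sequence.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"seq_id": str, "residue": str},
                         float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in _BASE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    has_label = "label" in df.columns

    profiles = []
    # sort=False keeps first-appearance file order
    for seq_id, grp in df.groupby("seq_id", sort=False):
        grp = grp.sort_values("position")
        pos = grp["position"].to_numpy()
        if not np.array_equal(pos, np.arange(1, len(grp) + 1)):
            raise FormatError(
                f"{path}: positions for {seq_id!r} are not contiguous from 1"
            )
        labels = None
        if has_label:
            labels = grp["label"].to_numpy()
            if not np.isin(labels, (0, 1)).all():
                raise FormatError(f"{path}: label outside {{0,1}} for {seq_id!r}")
        profiles.append(
            ScoreProfile(
                seq_id=str(seq_id),
                residues="".join(grp["residue"]),
                scores=grp[_SCORE_COLUMNS].to_numpy(float),
                labels=labels,
            )
        )
    return Dataset(profiles, provenance=f"read from {path}")


def write_score_table(dataset: Dataset, path) -> None:
    """Write a :class:`Dataset` back to the tab-separated table format."""
    rows = []
    for p in dataset:
        for i in range(len(p)):
            row = {
                "seq_id": p.seq_id,
                "position": i + 1,
                "residue": p.residues[i],
                **{f"score_{c}": repr(float(p.scores[i, j]))
                   for j, c in enumerate(CHANNELS)},
            }
            if p.labels is not None:
                row["label"] = p.labels[i]
            rows.append(row)
    cols = _BASE_COLUMNS + (["label"] if dataset.is_labelled else [])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def write_predictions(dataset: Dataset, probabilities, calls, path,
                      casp_style: bool = False) -> None:
    """Write per-residue disorder probabilities and binary calls as TSV.

    ``probabilities`` and ``calls`` are flat arrays aligned with the
    residues of ``dataset`` in profile order.  With ``casp_style`` a
    two-column (residue, probability) block per sequence is written
    instead of the default five-column table.
    """
    probabilities = np.asarray(probabilities, float)
    calls = np.asarray(calls, int)
    n = dataset.n_residues
    if probabilities.shape != (n,) or calls.shape != (n,):
        raise ValueError(
            f"predictions not aligned: {n} residues, "
            f"{probabilities.shape[0]} probabilities, {calls.shape[0]} calls"
        )
    if casp_style:
        with open(path, "w") as fh:
            off = 0
            for p in dataset:
                fh.write(f">{p.seq_id}\n")
                for i in range(len(p)):
                    fh.write(f"{p.residues[i]}\t{probabilities[off + i]:.6f}\n")
                off += len(p)
        return
    rows = []
    off = 0
    for p in dataset:
        for i in range(len(p)):
            rows.append(
                (p.seq_id, i + 1, p.residues[i],
                 f"{probabilities[off + i]:.6f}", calls[off + i])
            )
        off += len(p)
    pd.DataFrame(
        rows,
        columns=["seq_id", "position", "residue", "disorder_probability",
                 "binary_call"],
    ).to_csv(path, sep="\t", index=False)
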