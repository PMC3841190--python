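"""Structural-alphabet probability profiles: data model, TSV I/O, and a
stochastic pseudo-predictor that emulates sequence-based profile prediction.

For an N-residue chain the profile is an (N-3) x 27 matrix: row i holds the
probabilities that each alphabet letter describes the local conformation of
the 4-residue fragment starting at residue i.  Profiles decoded from a
structure are sharp; profiles predicted from sequence are much smoother.
``pseudo_predict`` reproduces that smoothing by resampling each row from a
Dirichlet centred on it, replacing the (out-of-scope) trained predictor for
testing and calibration.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "SAProfile",
    "ProfileParseError",
    "normalize_profile",
    "read_profile",
    "write_profile",
    "pseudo_predict",
    "DEFAULT_CONCENTRATION",
]

#: Default Dirichlet concentration of the pseudo-predictor; lower values
#: give smoother, noisier profiles (infinite concentration returns the
#: input).
DEFAULT_CONCENTRATION: float = 50.0

#: Additive floor on the Dirichlet parameter vector, keeping every letter
#: reachable and all rows strictly positive.
DIRICHLET_FLOOR: float = 0.01

_ROW_TOL = 1e-6


class ProfileParseError(ValueError):
    """Raised on malformed profile files; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


@dataclass
class SAProfile:
    """Per-position letter probabilities for one chain.

    rows : (n_rows, 27) array, each row a probability distribution.
    letter_order : the alphabet labels naming the columns.
    """

    source_id: str
    rows: np.ndarray
    letter_order: str

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=float)
        self.letter_order = "".join(self.letter_order)
        if self.rows.ndim != 2:
            self.rows = self.rows.reshape(0, len(self.letter_order))
        if self.rows.shape[1] != len(self.letter_order):
            raise ValueError(
                f"profile has {self.rows.shape[1]} columns but "
                f"{len(self.letter_order)} letters"
            )
        if self.n_rows and (
            np.min(self.rows) < -_ROW_TOL
            or np.max(np.abs(self.rows.sum(axis=1) - 1.0)) > _ROW_TOL
        ):
            raise ValueError("profile rows must be probability distributions")

    @property
    def n_rows(self) -> int:
        return self.rows.shape[0]

    def window(self, start_col: int, n_cols: int) -> np.ndarray:
        return self.rows[start_col : start_col + n_cols]


def normalize_profile(raw_rows: np.ndarray, source_id: str, letter_order: str) -> SAProfile:
    """Build an SAProfile by dividing each nonnegative row by its sum.

    Idempotent on already-normalized input.  Raises on negative entries and
    on all-zero rows (identifying the row index).
    """
    rows = np.asarray(raw_rows, dtype=float)
    if rows.ndim != 2:
        raise ValueError("expected a 2-D row array")
    if np.min(rows, initial=0.0) < 0:
        raise ValueError("negative entries in profile rows")
    sums = rows.sum(axis=1)
    zero = np.nonzero(sums <= 0)[0]
    if zero.size:
        raise ValueError(f"all-zero profile row at index {zero[0]}")
    return SAProfile(source_id, rows / sums[:, None], letter_order)


# ---------------------------------------------------------------------------
# Profile TSV v1
#
#   #SA-PROFILE 1 <source_id>
#   A<TAB>B<TAB>...           (letter labels)
#   1<TAB>p1<TAB>...<TAB>p27  (1-based position, probabilities %.6f)
# ---------------------------------------------------------------------------

def write_profile(profile: SAProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#SA-PROFILE 1 {profile.source_id}\n")
        fh.write("\t".join(profile.letter_order) + "\n")
        for i, row in enumerate(profile.rows, start=1):
            fh.write(str(i) + "\t" + "\t".join(f"{p:.6f}" for p in row) + "\n")


def read_profile(path: str | Path) -> SAProfile:
    """Parse a Profile TSV v1 file.  Rows are re-normalized to absorb the
    %.6f rounding, so write -> read is the identity to 1e-6 per entry."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("#SA-PROFILE 1"):
        raise ProfileParseError("missing '#SA-PROFILE 1' header", line=1)
    parts = lines[0].split(maxsplit=2)
    source_id = parts[2] if len(parts) > 2 else ""
    if len(lines) < 2:
        raise ProfileParseError("missing letter-label line", line=2)
    letters = lines[1].split("\t")
    if len(letters) != len(set(letters)) or any(len(c) != 1 for c in letters):
        raise ProfileParseError("letter labels must be unique single characters", line=2)
    n_letters = len(letters)
    rows = []
    for ln, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != n_letters + 1:
            raise ProfileParseError(
                f"expected {n_letters + 1} fields, got {len(fields)}", line=ln
            )
        try:
            pos = int(fields[0])
            vals = [float(x) for x in fields[1:]]
        except ValueError as exc:
            raise ProfileParseError(f"non-numeric field ({exc})", line=ln) from None
        if pos != len(rows) + 1:
            raise ProfileParseError(f"position index {pos} out of order", line=ln)
        rows.append(vals)
    if not rows:
        return SAProfile(source_id, np.zeros((0, n_letters)), "".join(letters))
    return normalize_profile(np.array(rows), source_id, "".join(letters))


# ---------------------------------------------------------------------------
# Pseudo-predictor
# ---------------------------------------------------------------------------

def pseudo_predict(
    true_posteriors: SAProfile,
    concentration: float = DEFAULT_CONCENTRATION,
    seed: int = 0,
) -> SAProfile:
    """Emulate sequence-based profile prediction by Dirichlet resampling.

    Each row p is replaced by a draw from Dirichlet(concentration * p +
    DIRICHLET_FLOOR).  The expected output row is the deterministic mixture
    (concentration * p + floor) / (concentration + 27 * floor); as the
    concentration grows the draw concentrates on the input row.
    """
    if concentration <= 0:
        raise ValueError("concentration must be > 0")
    rng = np.random.default_rng(seed)
    alphas = concentration * true_posteriors.rows + DIRICHLET_FLOOR
    rows = np.empty_like(true_posteriors.rows)
    for i, a in enumerate(alphas):
        rows[i] = rng.dirichlet(a)
    if rows.shape[0] == 0:
        return SAProfile(true_posteriors.source_id, rows, true_posteriors.letter_order)
    return normalize_profile(rows, true_posteriors.source_id, true_posteriors.letter_order)
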