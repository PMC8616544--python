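"""Count-matrix and sample-sheet I/O, and the nine-coefficient design matrix.

The experiment crosses two melanoma cell lines with eight conditions:
untreated control plus all seven nonempty combinations of three treatments
(TGFB = TGFbeta ligand, LATS = siRNA knockdown of LATS1/2, WNT = Wnt-3a
ligand).  Expression of a gene is modeled as

    y = b0 + b1*L + b2*TGFB + b3*LATS + b4*WNT
          + b5*(TGFB+LATS) + b6*(TGFB+WNT) + b7*(LATS+WNT)
          + b8*(TGFB+LATS+WNT)

with L an indicator for the second cell line and one indicator per nonempty
treatment combination, i.e. pairwise comparisons of each condition against
control that account for the cell-line difference.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

#: The three perturbed signaling nodes (S-genes), in fixed order.
NODES: tuple[str, ...] = ("TGFB", "LATS", "WNT")

#: The seven nonempty treatment combinations, in the fixed model order.
COMBOS: tuple[str, ...] = (
    "TGFB",
    "LATS",
    "WNT",
    "TGFB+LATS",
    "TGFB+WNT",
    "LATS+WNT",
    "TGFB+LATS+WNT",
)

#: Design-matrix column order: intercept, cell-line indicator, then COMBOS.
DESIGN_COLUMNS: tuple[str, ...] = ("intercept", "cell_line") + COMBOS

SAMPLE_COLUMNS = ("sample_id", "cell_line", "combo", "replicate")


def parse_combo(text: str) -> frozenset[str]:
    """Parse a plus-separated combination token; empty string is control."""
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return frozenset()
    text = str(text).strip()
    if not text:
        return frozenset()
    tokens = text.split("+")
    combo = frozenset(tokens)
    if not combo <= set(NODES) or len(tokens) != len(combo):
        raise ValueError(
            f"invalid treatment combination {text!r}: tokens must be unique "
            f"members of {set(NODES)}"
        )
    return combo


def combo_name(combo: frozenset[str]) -> str:
    """Canonical plus-separated name of a combination ('' for control)."""
    return "+".join(n for n in NODES if n in combo)


def all_conditions() -> list[frozenset[str]]:
    """The eight legal conditions: control plus the seven combinations."""
    return [frozenset()] + [parse_combo(c) for c in COMBOS]


# ---------------------------------------------------------------------------
# Counts I/O
# ---------------------------------------------------------------------------

def validate_counts(counts: pd.DataFrame) -> None:
    """Raise ValueError if `counts` violates the count-matrix invariants."""
    if counts.index.has_duplicates:
        dup = counts.index[counts.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r}")
    if counts.columns.has_duplicates:
        dup = counts.columns[counts.columns.duplicated()][0]
        raise ValueError(f"duplicate sample id {dup!r}")
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.integer):
        raise ValueError("counts must be integers")
    if (values < 0).any():
        g, s = np.argwhere(values < 0)[0]
        raise ValueError(
            f"negative count at gene {counts.index[g]!r}, sample "
            f"{counts.columns[s]!r}"
        )


def read_counts(path) -> pd.DataFrame:
    """Read a genes x samples TSV count matrix (header = sample ids,
    first column = gene ids) and validate it.

    Errors name the offending line (1-based, header = line 1) and cell.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.columns.has_duplicates:
        dup = raw.columns[raw.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r} in header")
    if raw.index.has_duplicates:
        pos = int(np.nonzero(raw.index.duplicated())[0][0])
        raise ValueError(
            f"{path}, line {pos + 2}: duplicate gene id {raw.index[pos]!r}"
        )
    values = np.empty(raw.shape, dtype=np.int64)
    for j, col in enumerate(raw.columns):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() | (converted != np.floor(converted.fillna(0)))
        if bad.any():
            pos = int(np.nonzero(bad.to_numpy())[0][0])
            raise ValueError(
                f"{path}, line {pos + 2}: non-integer count "
                f"{raw[col].iloc[pos]!r} for gene {raw.index[pos]!r}, "
                f"sample {col!r}"
            )
        neg = converted < 0
        if neg.any():
            pos = int(np.nonzero(neg.to_numpy())[0][0])
            raise ValueError(
                f"{path}, line {pos + 2}: negative count "
                f"{raw[col].iloc[pos]!r} for gene {raw.index[pos]!r}, "
                f"sample {col!r}"
            )
        values[:, j] = converted.astype(np.int64)
    counts = pd.DataFrame(values, index=raw.index, columns=raw.columns)
    counts.index.name = "gene_id"
    validate_counts(counts)
    return counts


def write_counts(counts: pd.DataFrame, path) -> None:
    """Write a count matrix as TSV (inverse of :func:`read_counts`)."""
    validate_counts(counts)
    out = counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Sample sheet I/O
# ---------------------------------------------------------------------------

def validate_samples(samples: pd.DataFrame, counts: pd.DataFrame | None = None) -> None:
    """Raise ValueError on sample-table invariant violations."""
    missing = set(SAMPLE_COLUMNS) - set(samples.columns)
    if missing:
        raise ValueError(f"sample table missing columns {sorted(missing)}")
    if samples["sample_id"].duplicated().any():
        dup = samples.loc[samples["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample id {dup!r}")
    lines = samples["cell_line"].unique()
    if len(lines) > 2:
        raise ValueError(f"expected at most 2 cell lines, found {sorted(lines)}")
    for combo in samples["combo"]:
        parse_combo(combo)  # raises on illegal token
    if (pd.to_numeric(samples["replicate"]) < 1).any():
        raise ValueError("replicate numbers must be positive")
    if counts is not None:
        absent = set(samples["sample_id"]) - set(counts.columns)
        if absent:
            raise ValueError(
                f"sample ids missing from count matrix: {sorted(absent)}"
            )


def read_samples(path, counts: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read a TSV sample sheet (sample_id, cell_line, combo, replicate)."""
    samples = pd.read_csv(
        path, sep="\t", dtype={"sample_id": str, "cell_line": str, "combo": str}
    )
    if "combo" in samples.columns:
        samples["combo"] = samples["combo"].fillna("")
    validate_samples(samples, counts)
    samples["replicate"] = samples["replicate"].astype(int)
    return samples.reset_index(drop=True)


def write_samples(samples: pd.DataFrame, path) -> None:
    validate_samples(samples)
    samples.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------

def build_design(samples: pd.DataFrame) -> pd.DataFrame:
    """Build the samples x 9 design matrix of the gene expression model.

    Columns follow :data:`DESIGN_COLUMNS`: intercept, cell-line indicator
    (reference level = lexicographically first cell-line label; the
    contrasts of interest are invariant to this choice), and one indicator
    per nonempty treatment combination.  A control sample of the reference
    line maps to the row (1, 0, ..., 0).
    """
    validate_samples(samples)
    lines = sorted(samples["cell_line"].unique())
    reference = lines[0]
    rows = np.zeros((len(samples), len(DESIGN_COLUMNS)))
    rows[:, 0] = 1.0
    combo_index = {parse_combo(c): i + 2 for i, c in enumerate(COMBOS)}
    for i, rec in enumerate(samples.itertuples(index=False)):
        if rec.cell_line != reference:
            rows[i, 1] = 1.0
        combo = parse_combo(rec.combo)
        if combo:
            rows[i, combo_index[combo]] = 1.0
    return pd.DataFrame(
        rows, index=pd.Index(samples["sample_id"], name="sample_id"),
        columns=list(DESIGN_COLUMNS),
    )
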