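"""Community-state typing of cervicovaginal microbiome abundance tables.

A sample is labelled ``L`` (Lactobacilli-dominated) when the combined
relative abundance of the four physiological *Lactobacillus* species —
*L. crispatus*, *L. gasseri*, *L. iners*, *L. jensenii* — is at least the
threshold (default 50%), and ``O`` (Other) below it.  This binary label is
the outcome the methylation signature predicts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

#: the four designated Lactobacillus species defining community-type L
DEFAULT_LACTOBACILLI = (
    "Lactobacillus crispatus",
    "Lactobacillus gasseri",
    "Lactobacillus iners",
    "Lactobacillus jensenii",
)


def _canon(name: str) -> str:
    return " ".join(str(name).strip().lower().split())


def normalize_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Convert a samples × taxa count (or fraction) table to relative abundance.

    Each row is divided by its sum.  Already-normalised input passes through
    unchanged up to floating point.

    Raises
    ------
    ValueError
        If any sample row sums to zero (names the offending samples).
    """
    values = counts.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("abundance table contains negative values")
    row_sums = values.sum(axis=1)
    zero = row_sums <= 0
    if zero.any():
        bad = list(counts.index[zero])
        raise ValueError(f"all-zero abundance row(s) for sample(s): {bad}")
    return pd.DataFrame(
        values / row_sums[:, None], index=counts.index, columns=counts.columns
    )


def assign_community_type(
    table: pd.DataFrame,
    lactobacilli: tuple[str, ...] = DEFAULT_LACTOBACILLI,
    threshold: float = 0.5,
    synonym_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Assign the binary L/O community-type label per sample.

    Parameters
    ----------
    table
        Samples × taxa relative abundances (rows should sum to 1; counts are
        normalised first).
    lactobacilli
        Taxon names whose summed abundance defines the Lactobacillus
        fraction.  Matching is case- and whitespace-insensitive.
    threshold
        Minimum Lactobacillus fraction for label ``L``; the boundary value is
        inclusive ("at least" the threshold maps to L).
    synonym_map
        Optional mapping from observed taxon names to canonical ones.

    Returns
    -------
    DataFrame indexed by sample with columns ``label`` ('L'/'O') and
    ``lactobacillus_fraction``.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    table = normalize_abundance(table)

    rename = {k: v for k, v in (synonym_map or {}).items()}
    columns = [_canon(rename.get(c, c)) for c in table.columns]
    wanted = {_canon(t) for t in lactobacilli}
    present = [i for i, c in enumerate(columns) if c in wanted]
    missing = wanted - {columns[i] for i in present}
    if missing:
        warnings.warn(
            f"designated Lactobacillus taxa absent from table (contribute 0): "
            f"{sorted(missing)}",
            stacklevel=2,
        )
    frac = table.iloc[:, present].to_numpy().sum(axis=1) if present else np.zeros(len(table))
    labels = np.where(frac >= threshold, "L", "O")
    return pd.DataFrame(
        {"label": labels, "lactobacillus_fraction": frac}, index=table.index
    )
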