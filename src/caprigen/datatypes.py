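"""Core in-memory containers shared across the pipeline.

Genotypes are stored as alternate-allele dosages (0/1/2) with an explicit
missingness mask; phenotypes live in a pandas DataFrame keyed by sample id
with trait values in cm plus the two fixed-effect covariates used throughout
(milk production status and birth year).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING_DOSAGE = -1


@dataclass
class GenotypeMatrix:
    """Individuals x markers allele-dosage table.

    ``dosages`` holds integers in {0, 1, 2}; entries flagged in ``missing``
    are undefined (stored as -1). ``marker_meta`` carries per-marker
    chromosome, position and alleles, indexed like ``marker_ids``.
    """

    sample_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray
    missing: np.ndarray
    marker_meta: pd.DataFrame = field(default=None)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int16)
        self.missing = np.asarray(self.missing, dtype=bool)
        n, m = self.dosages.shape
        if len(self.sample_ids) != n or len(self.marker_ids) != m:
            raise ValueError("id lists inconsistent with dosage matrix shape")
        if self.missing.shape != (n, m):
            raise ValueError("missingness mask shape mismatch")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.marker_ids)) != m:
            raise ValueError("duplicate marker ids")
        valid = np.isin(self.dosages[~self.missing], (0, 1, 2))
        if not valid.all():
            raise ValueError("non-missing dosages must be 0, 1 or 2")
        if self.marker_meta is None:
            self.marker_meta = pd.DataFrame(
                {"chrom": "1", "pos": np.arange(1, m + 1), "ref": "A", "alt": "B"},
                index=pd.Index(self.marker_ids, name="marker_id"),
            )

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def dosage_float(self) -> np.ndarray:
        """Dosages as float with NaN at missing entries."""
        x = self.dosages.astype(float)
        x[self.missing] = np.nan
        return x

    def mean_imputed(self, freqs: np.ndarray | None = None) -> np.ndarray:
        """Dosages with missing entries replaced by 2p_j (the column mean).

        With ``freqs`` given, imputes to 2*freqs[j]; otherwise the per-marker
        mean of non-missing calls is used.
        """
        x = self.dosage_float()
        if freqs is None:
            col = np.nanmean(x, axis=0)
        else:
            col = 2.0 * np.asarray(freqs, dtype=float)
        idx = np.where(self.missing)
        x[idx] = col[idx[1]]
        return x

    def subset(self, sample_idx=None, marker_idx=None) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        mi = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in si],
            marker_ids=[self.marker_ids[j] for j in mi],
            dosages=self.dosages[np.ix_(si, mi)],
            missing=self.missing[np.ix_(si, mi)],
            marker_meta=self.marker_meta.iloc[mi],
        )


@dataclass
class PhenotypeTable:
    """Per-individual trait values plus fixed-effect covariates.

    ``data`` is indexed by sample id and holds one column per trait (cm),
    a ``milk_status`` column and a ``birth_year`` column (both categorical).
    ``true_breeding_values``, present for simulated data only, records the
    total genetic value of each individual for each trait.
    """

    data: pd.DataFrame
    trait_names: list[str]
    true_breeding_values: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValueError("duplicate sample ids in phenotype table")
        for col in (*self.trait_names, "milk_status", "birth_year"):
            if col not in self.data.columns:
                raise ValueError(f"phenotype table missing column {col!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def values(self, trait: str | int) -> np.ndarray:
        if isinstance(trait, int):
            trait = self.trait_names[trait]
        return self.data[trait].to_numpy(dtype=float)

    def subset(self, sample_ids) -> "PhenotypeTable":
        tbv = None
        if self.true_breeding_values is not None:
            tbv = self.true_breeding_values.loc[sample_ids]
        return PhenotypeTable(self.data.loc[sample_ids], list(self.trait_names), tbv)


@dataclass
class RelationshipMatrix:
    """Symmetric genome-derived relationship matrix G.

    ``denominator`` is the VanRaden scaling constant sum(2 p_j q_j);
    ``blend_weight`` is 1.0 for a raw G and w after blending w*G + (1-w)*I.
    """

    sample_ids: list[str]
    values: np.ndarray
    denominator: float
    blend_weight: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise ValueError("G dimension does not match sample count")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("G is not symmetric")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def index_of(self, ids) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return np.array([lookup[s] for s in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"sample id {e.args[0]!r} not in relationship matrix")

    def submatrix(self, row_ids, col_ids=None) -> np.ndarray:
        ri = self.index_of(row_ids)
        ci = ri if col_ids is None else self.index_of(col_ids)
        return self.values[np.ix_(ri, ci)]

    def reorder(self, sample_ids) -> "RelationshipMatrix":
        idx = self.index_of(sample_ids)
        return RelationshipMatrix(
            list(sample_ids), self.values[np.ix_(idx, idx)],
            self.denominator, self.blend_weight,
        )
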