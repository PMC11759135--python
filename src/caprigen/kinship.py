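"""Allele frequencies and the VanRaden genomic relationship matrix.

G = M M' / sum_j 2 p_j q_j, where M is the allele-frequency-centered dosage
matrix (column j takes values 0-2p_j, 1-2p_j, 2-2p_j) and p_j is the
frequency of the allele counted by the dosage. Under Hardy-Weinberg
equilibrium the expected diagonal of G is 1, so entries read as genomic
relationships on the usual numerator-relationship scale. The same matrix
serves as the GBLUP covariance structure and, row-wise, as the feature
representation handed to the machine-learning predictors.
"""

from __future__ import annotations

import numpy as np

from .datatypes import GenotypeMatrix, RelationshipMatrix


def allele_frequencies(genotypes: GenotypeMatrix) -> np.ndarray:
    """Per-marker frequency of the counted (alternate) allele.

    p_j = mean non-missing dosage at marker j, divided by 2.
    """
    x = genotypes.dosage_float()
    n_called = (~genotypes.missing).sum(axis=0)
    if (n_called == 0).any():
        bad = int(np.argmax(n_called == 0))
        raise ValueError(
            f"marker {genotypes.marker_ids[bad]!r} has no non-missing calls"
        )
    return np.nanmean(x, axis=0) / 2.0


def vanraden_g(
    genotypes: GenotypeMatrix, freqs: np.ndarray | None = None
) -> RelationshipMatrix:
    """Compute G = MM' / sum(2 p q) from dosages and allele frequencies.

    Missing dosages are mean-imputed to 2p_j, i.e. to zero after centering,
    which keeps the denominator consistent across all entries. Monomorphic
    markers (p in {0, 1}) must be filtered beforehand: they contribute
    nothing to the numerator yet would not be estimable.
    """
    if freqs is None:
        freqs = allele_frequencies(genotypes)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (genotypes.n_markers,):
        raise ValueError("frequency vector length does not match marker count")
    if ((freqs <= 0.0) | (freqs >= 1.0)).any():
        raise ValueError(
            "allele frequencies must lie strictly in (0, 1); "
            "remove monomorphic markers before computing G"
        )
    denom = float(np.sum(2.0 * freqs * (1.0 - freqs)))
    if denom <= 0.0:
        raise ValueError("zero VanRaden denominator")
    m = genotypes.mean_imputed(freqs) - 2.0 * freqs
    g = (m @ m.T) / denom
    g = (g + g.T) / 2.0  # enforce exact symmetry against fp round-off
    return RelationshipMatrix(list(genotypes.sample_ids), g, denom, 1.0)


def blend(G: RelationshipMatrix, weight: float = 0.95) -> RelationshipMatrix:
    """Blend with the identity: weight*G + (1-weight)*I.

    Restores strict positive definiteness (the raw G is rank-deficient
    whenever markers < samples or duplicates are present); the smallest
    eigenvalue after blending is at least 1 - weight.
    """
    if not (0.0 < weight <= 1.0):
        raise ValueError("blend weight must lie in (0, 1]")
    values = weight * G.values + (1.0 - weight) * np.eye(G.n_samples)
    return RelationshipMatrix(list(G.sample_ids), values, G.denominator, weight)
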