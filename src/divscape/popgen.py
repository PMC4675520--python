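"""Population-genetic statistics for codominant diploid SSR genotypes.

The central objects are :class:`GenotypeTable` — individuals x loci, two
integer allele calls per cell, 0 encoding a missing pair — and the
locally-common-allele (LCA) classifier. An LCA is an allele that reaches
appreciable frequency (default > 5%) in only a small fraction (default
< 25%) of the occupied range; a concentration of such alleles marks
populations with a history of isolation, e.g. in glacial refugia.

Heterozygosity follows the plain Nei gene-diversity formula
``He = 1 - sum(p_a^2)`` with no small-sample correction: downstream cell
statistics are always computed on fixed-size subsamples, where the
correction is a constant factor. The fixation index is ``Fis = 1 - Ho/He``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo import pairwise_haversine_km

__all__ = [
    "GenotypeTable",
    "LocusSummary",
    "LCACatalog",
    "allele_frequencies",
    "expected_heterozygosity",
    "observed_heterozygosity",
    "fixation_index",
    "locus_summaries",
    "allele_sharing_distance",
    "mantel_test",
    "classify_lca",
]


@dataclass
class GenotypeTable:
    """Diploid codominant genotypes with per-individual coordinates.

    Parameters
    ----------
    ids : sequence of str
        Individual identifiers, in row order.
    loci : sequence of str
        Locus names, in column order.
    calls : ndarray of shape (n_individuals, n_loci, 2), int
        Unordered allele-label pairs; both entries 0 means missing.
        Allele labels are positive integers.
    coords : ndarray of shape (n_individuals, 2)
        Longitude, latitude in decimal degrees.
    """

    ids: list[str]
    loci: list[str]
    calls: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.ids = list(self.ids)
        self.loci = list(self.loci)
        self.calls = np.asarray(self.calls, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        n, L = len(self.ids), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(f"calls shape {self.calls.shape} != {(n, L, 2)}")
        if self.coords.shape != (n, 2):
            raise ValueError("every individual must have (lon, lat) coordinates")
        if np.any(self.calls < 0):
            raise ValueError("allele labels must be positive (0 = missing)")
        half_missing = (self.calls == 0).sum(axis=2) == 1
        if half_missing.any():
            raise ValueError("an individual is missing at a locus only as a whole pair")
        self._index = {i: k for k, i in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def missing_mask(self) -> np.ndarray:
        """(n, L) boolean: True where the call pair is missing."""
        return np.all(self.calls == 0, axis=2)

    def rows(self, subset) -> np.ndarray:
        try:
            return np.array([self._index[i] for i in subset], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown individual id {exc.args[0]!r}") from None

    def subset(self, ids) -> "GenotypeTable":
        rows = self.rows(ids)
        return GenotypeTable(
            [self.ids[r] for r in rows], self.loci, self.calls[rows], self.coords[rows]
        )


def allele_frequencies(table: GenotypeTable, subset=None) -> dict[str, dict[int, float]]:
    """Per-locus allele frequencies over a subset of individuals.

    Counts allele copies over ``2 x`` the non-missing individuals at each
    locus. Loci with no scored individual in the subset are omitted from
    the result (the caller can detect them by key absence).
    """
    rows = np.arange(table.n) if subset is None else table.rows(subset)
    if rows.size == 0:
        raise ValueError("empty subset")
    out: dict[str, dict[int, float]] = {}
    for j, locus in enumerate(table.loci):
        pairs = table.calls[rows, j, :]
        copies = pairs[pairs > 0]
        if copies.size == 0:
            continue
        labels, counts = np.unique(copies, return_counts=True)
        total = counts.sum()
        out[locus] = {int(a): c / total for a, c in zip(labels, counts)}
    return out


def expected_heterozygosity(freqs: dict[int, float]) -> float:
    """Nei gene diversity ``He = 1 - sum p_a^2`` for one locus."""
    if not freqs:
        raise ValueError("empty frequency map: He undefined")
    p = np.array(list(freqs.values()), dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError(f"frequencies sum to {p.sum()}, expected 1")
    return float(1.0 - np.sum(p**2))


def observed_heterozygosity(table: GenotypeTable, subset=None) -> tuple[dict[str, float], float]:
    """Per-locus fraction of scored individuals whose two calls differ, and its mean.

    The mean weights loci equally; loci with no scored individual are skipped.
    """
    rows = np.arange(table.n) if subset is None else table.rows(subset)
    if rows.size == 0:
        raise ValueError("empty subset")
    per_locus: dict[str, float] = {}
    for j, locus in enumerate(table.loci):
        pairs = table.calls[rows, j, :]
        scored = pairs[:, 0] > 0
        if not scored.any():
            continue
        het = pairs[scored, 0] != pairs[scored, 1]
        per_locus[locus] = float(het.mean())
    if not per_locus:
        raise ValueError("no scored locus in subset")
    return per_locus, float(np.mean(list(per_locus.values())))


def fixation_index(he: float, ho: float) -> float:
    """Fixation index ``Fis = 1 - Ho/He``; undefined for monomorphic loci."""
    if he < 0:
        raise ValueError("He must be nonnegative")
    if he == 0:
        raise ZeroDivisionError("He = 0 (monomorphic locus): Fis undefined")
    return 1.0 - ho / he


@dataclass
class LocusSummary:
    """Per-locus summary: allele count, frequencies, He, Ho, Fis."""

    locus: str
    allele_count: int
    freqs: dict[int, float]
    He: float
    Ho: float
    Fis: float | None


def locus_summaries(table: GenotypeTable, subset=None) -> pd.DataFrame:
    """Summary table of allele number, He, Ho and Fis for every scored locus."""
    freqs = allele_frequencies(table, subset)
    ho_per_locus, _ = observed_heterozygosity(table, subset)
    recs = []
    for locus, f in freqs.items():
        he = expected_heterozygosity(f)
        ho = ho_per_locus[locus]
        fis = np.nan if he == 0 else fixation_index(he, ho)
        recs.append(
            {"locus": locus, "allele_count": len(f), "He": he, "Ho": ho, "Fis": fis}
        )
    return pd.DataFrame(recs).set_index("locus")


# -- distances and Mantel ---------------------------------------------------


def allele_sharing_distance(table: GenotypeTable) -> np.ndarray:
    """Pairwise allele-sharing distance between individuals.

    For each locus scored in both individuals, similarity is the number of
    shared allele copies (0, 1 or 2) over 2; the distance is one minus the
    mean similarity over scored loci. Parameter-free and standard for SSR
    data at the individual level.
    """
    n, L = table.n, len(table.loci)
    d = np.zeros((n, n))
    calls = table.calls
    missing = table.missing_mask
    for i in range(n):
        for k in range(i + 1, n):
            sims = []
            for j in range(L):
                if missing[i, j] or missing[k, j]:
                    continue
                a = calls[i, j]
                b = calls[k, j]
                # shared copies between two unordered pairs
                shared = 0
                b_pool = list(b)
                for allele in a:
                    if allele in b_pool:
                        shared += 1
                        b_pool.remove(allele)
                sims.append(shared / 2.0)
            dist = 1.0 - float(np.mean(sims)) if sims else np.nan
            d[i, k] = d[k, i] = dist
    return d


def geographic_distance_matrix(table: GenotypeTable) -> np.ndarray:
    """Great-circle distance matrix (km) between individuals."""
    return pairwise_haversine_km(table.coords[:, 0], table.coords[:, 1])


def mantel_test(
    dist_a: np.ndarray,
    dist_b: np.ndarray,
    permutations: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices with a permutation p-value.

    ``r`` is the Pearson correlation of the upper off-diagonal triangles;
    the null distribution is built by jointly permuting rows and columns of
    the second matrix, and ``p = (1 + #{r_perm >= r_obs}) / (perms + 1)``
    (one-sided, as used for isolation-by-distance). When ``n!`` does not
    exceed ``permutations`` the full permutation group is enumerated
    instead and the p-value is exact: ``#{r_perm >= r_obs} / n!``.
    """
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    n = a.shape[0]
    if a.shape != (n, n) or b.shape != (n, n) or n < 4:
        raise ValueError("need two square matrices of order >= 4")
    for m, name in ((a, "dist_a"), (b, "dist_b")):
        if not np.allclose(m, m.T, equal_nan=True):
            raise ValueError(f"{name} is not symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError(f"{name} has a nonzero diagonal")
    iu = np.triu_indices(n, k=1)
    x = a[iu]
    y = b[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant distance matrix: Mantel r undefined")
    xc = (x - x.mean()) / x.std()
    yc = (y - y.mean()) / y.std()
    r_obs = float(np.mean(xc * yc))

    def perm_r(perm) -> float:
        yp = b[np.ix_(perm, perm)][iu]
        yp = (yp - yp.mean()) / yp.std()
        return float(np.mean(xc * yp))

    import math

    if math.factorial(n) <= permutations:  # small n: exact enumeration
        import itertools

        rs = [perm_r(np.array(perm)) for perm in itertools.permutations(range(n))]
        hits = sum(r >= r_obs - 1e-12 for r in rs)
        return r_obs, hits / len(rs)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        if perm_r(rng.permutation(n)) >= r_obs - 1e-12:
            hits += 1
    return r_obs, (1 + hits) / (permutations + 1)


# -- locally common alleles -------------------------------------------------


@dataclass
class LCACatalog:
    """Classification of every (locus, allele) pair against the LCA definition."""

    entries: pd.DataFrame
    freq_threshold: float = 0.05
    area_threshold: float = 0.25
    n_occupied_cells: int = 0

    def lca_set(self) -> set[tuple[str, int]]:
        sel = self.entries[self.entries["is_lca"]]
        return {(r.locus, int(r.allele)) for r in sel.itertuples()}


def classify_lca(
    table: GenotypeTable,
    occupied_cells: dict,
    freq_threshold: float = 0.05,
    area_threshold: float = 0.25,
) -> LCACatalog:
    """Classify alleles as locally common over a cell-level discretization.

    Parameters
    ----------
    occupied_cells : mapping cell id -> list of individual ids
        The occupied-range discretization: every cell holding at least one
        individual. The "distribution area" denominator is the number of
        such cells.
    freq_threshold, area_threshold : float
        An allele is an LCA iff its within-cell frequency exceeds
        ``freq_threshold`` in at least one cell, but in fewer than
        ``area_threshold`` of all occupied cells.
    """
    cells = {c: ids for c, ids in occupied_cells.items() if len(ids) > 0}
    if not cells:
        raise ValueError("no occupied cells")
    n_cells = len(cells)
    cell_freqs = {c: allele_frequencies(table, ids) for c, ids in cells.items()}
    recs = []
    for j, locus in enumerate(table.loci):
        copies = table.calls[:, j, :]
        alleles = np.unique(copies[copies > 0])
        for allele in alleles:
            qualifying = [
                c
                for c, fr in cell_freqs.items()
                if fr.get(locus, {}).get(int(allele), 0.0) > freq_threshold
            ]
            frac = len(qualifying) / n_cells
            is_lca = 0.0 < frac < area_threshold
            recs.append(
                {
                    "locus": locus,
                    "allele": int(allele),
                    "is_lca": is_lca,
                    "occupied_fraction": frac,
                    "qualifying_cells": tuple(qualifying),
                }
            )
    entries = pd.DataFrame(recs)
    return LCACatalog(entries, freq_threshold, area_threshold, n_cells)
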