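"""Core data containers: genotype dosage matrices and phenotype tables."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

N_LEVELS = ("LN", "HN")


@dataclass
class GenotypeMatrix:
    """Genotypes x markers alternate-allele dosage matrix.

    ``dosage`` holds counts of the alternate allele in {0, 1, 2}; missing
    calls are ``np.nan``.  ``marker_meta`` optionally carries per-marker
    chromosome and position.
    """

    genotype_ids: list[str]
    marker_ids: list[str]
    dosage: np.ndarray  # float array, nan = missing
    marker_meta: pd.DataFrame | None = None
    imputed: bool = False  # mean-imputed matrices may hold fractional dosages

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if len(self.genotype_ids) != n:
            raise ValueError(
                f"{len(self.genotype_ids)} genotype ids for {n} dosage rows"
            )
        if len(self.marker_ids) != m:
            raise ValueError(f"{len(self.marker_ids)} marker ids for {m} columns")
        if len(set(self.genotype_ids)) != n:
            raise ValueError("genotype ids are not unique")
        if len(set(self.marker_ids)) != m:
            raise ValueError("marker ids are not unique")
        obs = self.dosage[~np.isnan(self.dosage)]
        if self.imputed:
            if obs.size and ((obs < 0) | (obs > 2)).any():
                raise ValueError("dosages must lie in [0, 2]")
        elif obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValueError("non-missing dosages must be in {0, 1, 2}")

    @property
    def n_genotypes(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.dosage)

    def subset_markers(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        meta = None
        if self.marker_meta is not None:
            meta = self.marker_meta.iloc[keep].reset_index(drop=True)
        return GenotypeMatrix(
            genotype_ids=list(self.genotype_ids),
            marker_ids=[self.marker_ids[i] for i in keep],
            dosage=self.dosage[:, keep].copy(),
            marker_meta=meta,
            imputed=self.imputed,
        )

    def subset_genotypes(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            genotype_ids=[self.genotype_ids[i] for i in keep],
            marker_ids=list(self.marker_ids),
            dosage=self.dosage[keep, :].copy(),
            marker_meta=self.marker_meta,
            imputed=self.imputed,
        )


@dataclass
class PhenotypeTable:
    """Per genotype x nitrogen-level trait records.

    Columns: ``genotype_id``, ``n_level`` (LN/HN), ``GY`` grain yield (g/m2),
    ``Ns`` nitrogen supplied, ``Nt`` total above-ground plant nitrogen at
    maturity, ``NUE`` the unitless ratio GY/Ns.
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("genotype_id", "n_level", "GY", "Ns", "Nt", "NUE")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        bad = set(self.table["n_level"]) - set(N_LEVELS)
        if bad:
            raise ValueError(f"unknown n_level values: {sorted(bad)}")
        ok = self.table["Ns"] > 0
        ratio = self.table.loc[ok, "GY"] / self.table.loc[ok, "Ns"]
        if not np.allclose(ratio, self.table.loc[ok, "NUE"], rtol=1e-8, atol=1e-10):
            raise ValueError("NUE column inconsistent with GY / Ns")

    def trait(self, n_level: str, genotype_ids: list[str] | None = None) -> np.ndarray:
        """NUE vector for one N level, ordered by ``genotype_ids``."""
        sub = self.table[self.table["n_level"] == n_level]
        ser = sub.set_index("genotype_id")["NUE"]
        if genotype_ids is None:
            return ser.to_numpy(dtype=float)
        return ser.loc[list(genotype_ids)].to_numpy(dtype=float)
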