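"""Core containers shared across simulation, truth, reconstruction and estimation.

Genotypes are coded as counts of the minor allele, ``{0, 1, 2}``, with ``-1``
for missing. Dyad (offspring-pair) relationships are coded ``U=0`` (unrelated,
no shared parent), ``HS=1`` (half-sib, exactly one shared parent) and ``FS=2``
(full-sib, both parents shared).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = -1

DYAD_U = 0
DYAD_HS = 1
DYAD_FS = 2
DYAD_NAMES = {DYAD_FS: "FS", DYAD_HS: "HS", DYAD_U: "U"}

MONOGAMY = "monogamy"
MALE_POLYGAMY_FEMALE_MONOGAMY = "male_polygamy_female_monogamy"
POLYGAMY = "polygamy"
MATING_SYSTEMS = (MONOGAMY, MALE_POLYGAMY_FEMALE_MONOGAMY, POLYGAMY)


class PedigreeError(ValueError):
    pass


@dataclass
class Pedigree:
    """A complete breeding record: parent roster, mating units and offspring.

    ``parents`` maps parent ID -> sex ("M"/"F") and may include parents that
    produced no offspring. ``crosses`` are (sires, dams) mating units; a
    monogamous cross has one sire and one dam, a contaminated 2x2 cross-matrix
    has two of each. ``offspring`` maps offspring ID -> (sire ID, dam ID).
    """

    parents: dict[str, str]
    crosses: list[tuple[tuple[str, ...], tuple[str, ...]]]
    offspring: dict[str, tuple[str, str]]

    def validate(self) -> None:
        for oid, (sire, dam) in self.offspring.items():
            if sire not in self.parents or dam not in self.parents:
                raise PedigreeError(f"offspring {oid} has parents absent from roster")
            if self.parents[sire] != "M":
                raise PedigreeError(f"sire {sire} of {oid} is not male")
            if self.parents[dam] != "F":
                raise PedigreeError(f"dam {dam} of {oid} is not female")

    @property
    def offspring_ids(self) -> list[str]:
        return list(self.offspring)

    @property
    def n_offspring(self) -> int:
        return len(self.offspring)

    def parent_arrays(self, sample: list[str] | None = None) -> tuple[list[str], np.ndarray, np.ndarray]:
        """Integer-coded sire and dam arrays for a sample of offspring."""
        ids = list(self.offspring) if sample is None else list(sample)
        sire_code: dict[str, int] = {}
        dam_code: dict[str, int] = {}
        sires = np.empty(len(ids), dtype=np.int64)
        dams = np.empty(len(ids), dtype=np.int64)
        for k, oid in enumerate(ids):
            try:
                sire, dam = self.offspring[oid]
            except KeyError:
                raise PedigreeError(f"unknown offspring id {oid!r}") from None
            sires[k] = sire_code.setdefault(sire, len(sire_code))
            dams[k] = dam_code.setdefault(dam, len(dam_code))
        return ids, sires, dams


@dataclass
class GenotypeTable:
    """Individuals x loci minor-allele-count codes with simulation frequencies.

    ``codes`` is an ``(n, L)`` int8 array in {0, 1, 2, MISSING}. ``sim_freqs``
    holds the per-locus minor-allele frequency used in simulation when the
    table was simulated (``None`` for tables read from disk).
    """

    ids: list[str]
    loci: list[str]
    codes: np.ndarray
    sim_freqs: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.ids), len(self.loci)):
            raise ValueError("genotype matrix shape inconsistent with ids/loci")
        bad = ~np.isin(self.codes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("invalid genotype codes (expected 0/1/2/missing)")
        if self.sim_freqs is not None:
            self.sim_freqs = np.asarray(self.sim_freqs, dtype=float)
            if self.sim_freqs.shape != (len(self.loci),):
                raise ValueError("sim_freqs length inconsistent with loci")
            if np.any((self.sim_freqs <= 0) | (self.sim_freqs >= 1)):
                raise ValueError("simulation allele frequencies must lie in (0,1)")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def subset(self, ids: list[str]) -> "GenotypeTable":
        index = {i: k for k, i in enumerate(self.ids)}
        rows = np.array([index[i] for i in ids], dtype=np.int64)
        return GenotypeTable(list(ids), list(self.loci), self.codes[rows], self.sim_freqs)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.codes, columns=self.loci)
        df = df.mask(df == MISSING).astype("Int64")
        df.insert(0, "individual_id", self.ids)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeTable":
        if df.columns[0] != "individual_id":
            raise ValueError("genotype table must start with an 'individual_id' column")
        ids = df["individual_id"].astype(str).tolist()
        loci = [str(c) for c in df.columns[1:]]
        codes = df[df.columns[1:]].to_numpy(dtype=float)
        codes = np.where(np.isnan(codes), MISSING, codes).astype(np.int8)
        return cls(ids, loci, codes)


@dataclass
class KiVector:
    """Per-parent counts of sampled offspring; sum(ki) = 2S for S offspring."""

    counts: dict[str, int]
    S: int

    def __post_init__(self) -> None:
        if any(k < 0 for k in self.counts.values()):
            raise ValueError("ki counts must be non-negative")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def values(self) -> np.ndarray:
        return np.array(list(self.counts.values()), dtype=np.int64)


@dataclass
class DyadLabelSet:
    """Labels for every unordered offspring pair, stored condensed.

    ``labels`` is a length-C(n,2) uint8 array in upper-triangular (i<j) order
    matching ``ids``. ``hs_paternal``/``hs_maternal`` split the HS count into
    share-sire-only and share-dam-only dyads (needed for Q1/Q2).
    """

    ids: list[str]
    labels: np.ndarray
    hs_paternal: int = 0
    hs_maternal: int = 0

    def __post_init__(self) -> None:
        n = len(self.ids)
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.shape != (n * (n - 1) // 2,):
            raise ValueError("condensed label vector has wrong length")

    @classmethod
    def from_parent_codes(cls, ids: list[str], sires: np.ndarray, dams: np.ndarray) -> "DyadLabelSet":
        n = len(ids)
        iu, ju = np.triu_indices(n, 1)
        same_sire = sires[iu] == sires[ju]
        same_dam = dams[iu] == dams[ju]
        labels = (same_sire.astype(np.uint8) + same_dam.astype(np.uint8))
        hs_pat = int(np.count_nonzero(same_sire & ~same_dam))
        hs_mat = int(np.count_nonzero(~same_sire & same_dam))
        return cls(list(ids), labels, hs_pat, hs_mat)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_dyads(self) -> int:
        return self.labels.shape[0]

    @property
    def counts(self) -> dict[str, int]:
        c = np.bincount(self.labels, minlength=3)
        return {"FS": int(c[DYAD_FS]), "HS": int(c[DYAD_HS]), "U": int(c[DYAD_U])}

    def reordered(self, ids: list[str]) -> "DyadLabelSet":
        """The same label set expressed in a different individual order."""
        if set(ids) != set(self.ids):
            raise ValueError("individual sets differ")
        if list(ids) == self.ids:
            return self
        n = self.n
        square = np.zeros((n, n), dtype=np.uint8)
        iu, ju = np.triu_indices(n, 1)
        square[iu, ju] = self.labels
        square += square.T
        index = {i: k for k, i in enumerate(self.ids)}
        perm = np.array([index[i] for i in ids], dtype=np.int64)
        square = square[np.ix_(perm, perm)]
        return DyadLabelSet(list(ids), square[iu, ju], self.hs_paternal, self.hs_maternal)


@dataclass
class SibshipPartition:
    """Inferred sibship structure: latent sire/dam assignment per offspring.

    ``sires`` and ``dams`` are integer label arrays over separate namespaces
    (sire label 3 and dam label 3 are different parents). A full-sib cluster is
    a maximal set of offspring sharing both labels. Under monogamy each sire
    label pairs with exactly one dam label, so no half-sib dyads are derivable.
    """

    ids: list[str]
    sires: np.ndarray
    dams: np.ndarray
    mating_system: str = POLYGAMY
    log_likelihood: float | None = None
    approximate: bool = False

    def __post_init__(self) -> None:
        self.sires = np.asarray(self.sires, dtype=np.int64)
        self.dams = np.asarray(self.dams, dtype=np.int64)
        n = len(self.ids)
        if self.sires.shape != (n,) or self.dams.shape != (n,):
            raise ValueError("latent parent arrays inconsistent with ids")
        if self.mating_system == MONOGAMY:
            pairs_by_sire: dict[int, int] = {}
            pairs_by_dam: dict[int, int] = {}
            for s, d in zip(self.sires.tolist(), self.dams.tolist()):
                if pairs_by_sire.setdefault(s, d) != d or pairs_by_dam.setdefault(d, s) != s:
                    raise ValueError("monogamy partition has a parent shared across clusters")
        elif self.mating_system == MALE_POLYGAMY_FEMALE_MONOGAMY:
            sire_by_dam: dict[int, int] = {}
            for s, d in zip(self.sires.tolist(), self.dams.tolist()):
                if sire_by_dam.setdefault(d, s) != s:
                    raise ValueError("female-monogamy partition has a dam shared across sires")

    @property
    def n(self) -> int:
        return len(self.ids)

    def clusters(self) -> dict[tuple[int, int], list[int]]:
        """Full-sib clusters: (sire label, dam label) -> offspring indices."""
        out: dict[tuple[int, int], list[int]] = {}
        for k, (s, d) in enumerate(zip(self.sires.tolist(), self.dams.tolist())):
            out.setdefault((s, d), []).append(k)
        return out

    def cluster_sizes(self) -> list[int]:
        return sorted((len(v) for v in self.clusters().values()), reverse=True)

    @classmethod
    def from_clusters(cls, clusters: list[list[str]], mating_system: str = MONOGAMY) -> "SibshipPartition":
        ids: list[str] = []
        sires: list[int] = []
        for j, members in enumerate(clusters):
            ids.extend(members)
            sires.extend([j] * len(members))
        arr = np.array(sires, dtype=np.int64)
        return cls(ids, arr, arr.copy(), mating_system=mating_system)

    @classmethod
    def truth(cls, pedigree: Pedigree, sample: list[str] | None = None) -> "SibshipPartition":
        """The partition implied by a known pedigree (used as ground truth)."""
        ids, sires, dams = pedigree.parent_arrays(sample)
        return cls(ids, sires, dams, mating_system=POLYGAMY)


def replace(obj, **changes):
    """dataclasses.replace passthrough (convenience re-export)."""
    return dataclasses.replace(obj, **changes)
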