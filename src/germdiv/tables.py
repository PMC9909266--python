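"""In-memory containers for the three data layers and the primer panel.

The package analyses a germplasm collection through three parallel tables
sharing one set of genotype identifiers:

* :class:`BandMatrix` — dominant-marker fingerprints: genotypes x binary
  band calls (present/absent), each band owned by exactly one primer or
  primer combination.
* :class:`TraitTable` — mixed morphological phenotypes, each variable
  declared quantitative (numeric) or qualitative (finite ordered levels).
* :class:`ColorTable` — CIELab triplets (L*, a*, b*) measured per genotype
  and organ region (flower slip/eye/sepal, petiole, leaf lamina patterns),
  optionally extended with chroma C* and hue angle H°.

:class:`PrimerPanel` carries the primer records (name, 5'->3' sequence).
Band calls are stored as a float array with NaN encoding missing, the
usual numpy convention; validation enforces {0, 1, NaN}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlphabetError, EncodingError, FormatError

QUANTITATIVE = "quantitative"
QUALITATIVE = "qualitative"

_VALID_BASES = frozenset("ACGT")


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise FormatError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class BandMatrix:
    """Genotypes x binary band-presence calls, bands grouped by primer.

    Parameters
    ----------
    genotype_ids : list of str
        Ordered unique genotype labels (rows).
    band_ids : list of str
        Ordered unique band labels (columns).
    primer_of_band : dict
        Maps every band id to its owning primer name.
    calls : ndarray of shape (n_genotypes, n_bands)
        Values in {0.0, 1.0, NaN}; NaN encodes a missing call.
    """

    genotype_ids: list[str]
    band_ids: list[str]
    primer_of_band: dict[str, str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.genotype_ids = list(self.genotype_ids)
        self.band_ids = list(self.band_ids)
        _check_unique(self.genotype_ids, "genotype")
        _check_unique(self.band_ids, "band")
        if len(self.genotype_ids) < 2:
            raise FormatError("a band matrix needs at least 2 genotypes")
        if len(self.band_ids) < 1:
            raise FormatError("a band matrix needs at least 1 band")
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.genotype_ids), len(self.band_ids)):
            raise FormatError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.genotype_ids)} genotypes x {len(self.band_ids)} bands"
            )
        bad = ~(np.isnan(self.calls) | (self.calls == 0) | (self.calls == 1))
        if bad.any():
            i, j = map(int, np.argwhere(bad)[0])
            raise EncodingError(
                f"non-binary band call {self.calls[i, j]!r} at genotype "
                f"{self.genotype_ids[i]!r}, band {self.band_ids[j]!r}"
            )
        missing = set(self.band_ids) - set(self.primer_of_band)
        if missing:
            raise FormatError(f"bands without a primer assignment: {sorted(missing)}")

    @property
    def n_genotypes(self) -> int:
        return len(self.genotype_ids)

    @property
    def n_bands(self) -> int:
        return len(self.band_ids)

    @property
    def primers(self) -> list[str]:
        """Primer names in order of first appearance along the band axis."""
        out: list[str] = []
        for b in self.band_ids:
            p = self.primer_of_band[b]
            if p not in out:
                out.append(p)
        return out

    def bands_of_primer(self, primer: str) -> list[str]:
        return [b for b in self.band_ids if self.primer_of_band[b] == primer]

    def primer_calls(self, primer: str) -> np.ndarray:
        """Sub-matrix of calls restricted to one primer's bands."""
        cols = [self.band_ids.index(b) for b in self.bands_of_primer(primer)]
        return self.calls[:, cols]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.genotype_ids, columns=self.band_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BandMatrix):
            return NotImplemented
        return (
            self.genotype_ids == other.genotype_ids
            and self.band_ids == other.band_ids
            and self.primer_of_band == other.primer_of_band
            and np.array_equal(self.calls, other.calls, equal_nan=True)
        )


@dataclass
class PrimerRecord:
    name: str
    sequence: str
    annotation: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.strip().upper()
        if not self.sequence:
            raise AlphabetError(f"primer {self.name!r}: empty sequence")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise AlphabetError(
                f"primer {self.name!r}: invalid characters {sorted(bad)} "
                "(alphabet is A/C/G/T)"
            )

    @property
    def gc_percent(self) -> float:
        from .io_formats import gc_content

        return gc_content(self.sequence)


@dataclass
class PrimerPanel:
    """An ordered collection of uniquely named primer records."""

    records: list[PrimerRecord]

    def __post_init__(self) -> None:
        _check_unique([r.name for r in self.records], "primer")

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.records]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "primer": self.names,
                "sequence": [r.sequence for r in self.records],
                "gc_percent": [r.gc_percent for r in self.records],
                "annotation": [r.annotation for r in self.records],
            }
        )


@dataclass
class TraitTable:
    """Mixed quantitative/qualitative morphological traits.

    ``values`` is a genotype-indexed DataFrame; ``var_types`` declares each
    column quantitative or qualitative; qualitative columns carry an
    explicit ordered level list in ``levels`` (used for ordinal coding).
    Missing values are NaN (quantitative) or None/NaN (qualitative).
    """

    values: pd.DataFrame
    var_types: dict[str, str]
    levels: dict[str, list[str]] = field(default_factory=dict)
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _check_unique(list(self.values.index), "genotype")
        _check_unique(list(self.values.columns), "variable")
        for var in self.values.columns:
            t = self.var_types.get(var)
            if t not in (QUANTITATIVE, QUALITATIVE):
                raise FormatError(f"variable {var!r}: undeclared or invalid type {t!r}")
            col = self.values[var]
            if t == QUANTITATIVE:
                if not pd.api.types.is_numeric_dtype(col):
                    try:
                        self.values[var] = pd.to_numeric(col)
                    except (TypeError, ValueError) as exc:
                        raise EncodingError(
                            f"quantitative variable {var!r} has non-numeric values"
                        ) from exc
            else:
                declared = self.levels.get(var)
                observed = [str(v) for v in col.dropna().unique()]
                if declared is None:
                    self.levels[var] = sorted(observed)
                else:
                    extra = set(observed) - set(declared)
                    if extra:
                        raise EncodingError(
                            f"qualitative variable {var!r}: values {sorted(extra)} "
                            f"outside declared levels {declared}"
                        )

    @property
    def genotype_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def quantitative_vars(self) -> list[str]:
        return [v for v in self.values.columns if self.var_types[v] == QUANTITATIVE]

    @property
    def qualitative_vars(self) -> list[str]:
        return [v for v in self.values.columns if self.var_types[v] == QUALITATIVE]

    def ordinal_encoded(self) -> pd.DataFrame:
        """Numeric view: qualitative levels mapped to 0..L-1 by declared order."""
        out = {}
        for var in self.values.columns:
            if self.var_types[var] == QUANTITATIVE:
                out[var] = self.values[var].astype(float)
            else:
                codebook = {lv: i for i, lv in enumerate(self.levels[var])}
                out[var] = self.values[var].map(
                    lambda v: np.nan if pd.isna(v) else codebook[str(v)]
                )
        return pd.DataFrame(out, index=self.values.index).astype(float)


#: organ regions typically measured in ornamental-flower color phenotyping
DEFAULT_ORGANS = ("slip", "eye", "sepal", "petiole", "dark_lamina", "silver_lamina")


@dataclass
class ColorTable:
    """Long-format CIELab measurements: one row per genotype x organ region.

    Columns: genotype, organ, L, a, b and optionally C (chroma) and
    H (hue angle, degrees in [0, 360)). L* is bounded in [0, 100].
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = ["genotype", "organ", "L", "a", "b"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise FormatError(f"color table missing columns: {missing}")
        dup = self.data.duplicated(subset=["genotype", "organ"])
        if dup.any():
            row = self.data[dup].iloc[0]
            raise FormatError(
                f"duplicate color row for genotype {row['genotype']!r}, "
                f"organ {row['organ']!r}"
            )
        L = self.data["L"].astype(float)
        if ((L < 0) | (L > 100)).any():
            bad = self.data[(L < 0) | (L > 100)].iloc[0]
            raise EncodingError(
                f"L* out of [0,100] for genotype {bad['genotype']!r}, "
                f"organ {bad['organ']!r}: {bad['L']}"
            )
        if "H" in self.data.columns:
            H = self.data["H"].astype(float)
            ok = H.isna() | ((H >= 0) & (H < 360))
            if not ok.all():
                raise EncodingError("hue angle out of [0,360)")

    @property
    def genotype_ids(self) -> list[str]:
        return list(dict.fromkeys(self.data["genotype"]))

    @property
    def organs(self) -> list[str]:
        return list(dict.fromkeys(self.data["organ"]))
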