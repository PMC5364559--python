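"""Fixed-length numeric descriptor encodings of protein sequences.

Five schemes are provided:

========  ===========================================  ==========
scheme    meaning                                      dimension
========  ===========================================  ==========
AAC       residue frequencies                          20
DPC       overlapping di-peptide frequencies           400
PAAC      pseudo amino acid composition (Chou)         20 + lambda
CTD       composition/transition/distribution          21 per attribute
ACF       lagged physicochemical autocorrelations      M * n
========  ===========================================  ==========

Feature order is fixed and documented per scheme so trained models are
portable: alphabetical residues for AAC, nested alphabetical pairs for
DPC, attribute-then-block order for CTD and index-major-then-lag for ACF.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqio import AA_INDEX, AMINO_ACIDS, LabeledDataset, ProteinRecord

logger = logging.getLogger(__name__)

SCHEMES = ("AAC", "DPC", "PAAC", "CTD", "ACF")


class SequenceTooShortError(ValueError):
    """Sequence shorter than the scheme's minimum length."""


# ---------------------------------------------------------------------------
# physicochemical tables
# ---------------------------------------------------------------------------

# Chou's three classical per-residue properties used by the PAAC
# correlation factors (values in AMINO_ACIDS order ACDEFGHIKLMNPQRSTVWY).
_HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19, "G": 0.48,
    "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06, "M": 0.64, "N": -0.78,
    "P": 0.12, "Q": -0.85, "R": -2.53, "S": -0.18, "T": -0.05, "V": 1.08,
    "W": 0.81, "Y": 0.26,
}
_HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5, "G": 0.0,
    "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8, "M": -1.3, "N": 0.2,
    "P": 0.0, "Q": 0.2, "R": 3.0, "S": 0.3, "T": -0.4, "V": -1.5,
    "W": -3.4, "Y": -2.3,
}
_SIDE_CHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0, "G": 1.0,
    "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0, "M": 75.0, "N": 58.0,
    "P": 42.0, "Q": 72.0, "R": 101.0, "S": 31.0, "T": 45.0, "V": 43.0,
    "W": 130.0, "Y": 107.0,
}


def _property_array(table: Mapping[str, float]) -> np.ndarray:
    return np.array([table[aa] for aa in AMINO_ACIDS], dtype=float)


def standardize(values: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-sd (population) standardization over the 20 residues."""
    values = np.asarray(values, dtype=float)
    sd = values.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant property")
    return (values - values.mean()) / sd


# ---------------------------------------------------------------------------
# AAC / DPC
# ---------------------------------------------------------------------------

def aac_feature_names() -> list[str]:
    return list(AMINO_ACIDS)


def dpc_feature_names() -> list[str]:
    return [a + b for a in AMINO_ACIDS for b in AMINO_ACIDS]


def _seq_indices(record: ProteinRecord) -> np.ndarray:
    return np.fromiter(
        (AA_INDEX[c] for c in record.sequence), dtype=np.intp, count=record.length
    )


def encode_aac(record: ProteinRecord) -> np.ndarray:
    """Residue frequencies: component for residue a is count(a) / L."""
    counts = np.bincount(_seq_indices(record), minlength=20).astype(float)
    return counts / record.length


def encode_dpc(record: ProteinRecord) -> np.ndarray:
    """Overlapping di-peptide frequencies: count(ab) / (L - 1).

    Feature order is nested alphabetical (AA, AC, ..., YY).
    """
    if record.length < 2:
        raise SequenceTooShortError(
            f"DPC needs L >= 2, got L={record.length} for {record.id!r}"
        )
    idx = _seq_indices(record)
    pair_codes = idx[:-1] * 20 + idx[1:]
    counts = np.bincount(pair_codes, minlength=400).astype(float)
    return counts / (record.length - 1)


# ---------------------------------------------------------------------------
# PAAC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PaacParams:
    """Tier count, weight and the three standardized property vectors.

    ``properties`` has shape (3, 20): standardized hydrophobicity,
    hydrophilicity and side-chain mass in AMINO_ACIDS order.
    """

    lam: int = 1
    weight: float = 0.05
    properties: np.ndarray = field(
        default_factory=lambda: np.stack(
            [
                standardize(_property_array(_HYDROPHOBICITY)),
                standardize(_property_array(_HYDROPHILICITY)),
                standardize(_property_array(_SIDE_CHAIN_MASS)),
            ]
        )
    )

    def __post_init__(self) -> None:
        if self.lam < 1:
            raise ValueError(f"lambda must be >= 1, got {self.lam}")
        if self.weight <= 0:
            raise ValueError(f"weight must be > 0, got {self.weight}")
        props = np.asarray(self.properties, dtype=float)
        if props.shape != (3, 20):
            raise ValueError(f"properties must have shape (3, 20), got {props.shape}")
        if not np.allclose(props.mean(axis=1), 0.0, atol=1e-9):
            raise ValueError("properties must be standardized to mean 0")
        if not np.allclose(props.std(axis=1), 1.0, atol=1e-9):
            raise ValueError("properties must be standardized to sd 1")
        object.__setattr__(self, "properties", props)


def paac_theta(record: ProteinRecord, params: PaacParams, j: int) -> float:
    """Tier-j sequence-order correlation factor.

    theta_j = (1/(L-j)) * sum_i Theta(R_i, R_{i+j}) where Theta(a, b) is
    the mean squared difference of the three standardized property values.
    """
    if not 1 <= j <= params.lam:
        raise ValueError(f"tier j={j} outside 1..{params.lam}")
    if record.length < j + 1:
        raise SequenceTooShortError(
            f"theta_{j} needs L >= {j + 1}, got L={record.length} for {record.id!r}"
        )
    idx = _seq_indices(record)
    diff = params.properties[:, idx[j:]] - params.properties[:, idx[:-j]]
    return float((diff**2).mean(axis=0).mean())


def paac_feature_names(params: PaacParams) -> list[str]:
    return list(AMINO_ACIDS) + [f"theta{j}" for j in range(1, params.lam + 1)]


def encode_paac(record: ProteinRecord, params: PaacParams) -> np.ndarray:
    """(20 + lambda)-vector: composition and order factors share one denominator.

    With f_u the residue frequencies and D = sum_u f_u + w * sum_j theta_j,
    components are f_u / D followed by w * theta_j / D; the vector sums to 1.
    """
    if record.length < params.lam + 1:
        raise SequenceTooShortError(
            f"PAAC with lambda={params.lam} needs L >= {params.lam + 1}, "
            f"got L={record.length} for {record.id!r}"
        )
    freqs = encode_aac(record)
    thetas = np.array(
        [paac_theta(record, params, j) for j in range(1, params.lam + 1)]
    )
    denom = freqs.sum() + params.weight * thetas.sum()
    return np.concatenate([freqs, params.weight * thetas]) / denom


# ---------------------------------------------------------------------------
# CTD
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CtdGrouping:
    """A named 3-way partition of the 20 residues."""

    name: str
    group_of: Mapping[str, int]

    def __post_init__(self) -> None:
        missing = _AA_ORDER_SET - set(self.group_of)
        if missing:
            raise ValueError(f"grouping {self.name!r} misses {sorted(missing)}")
        groups = set(self.group_of[aa] for aa in AMINO_ACIDS)
        if groups != {1, 2, 3}:
            raise ValueError(
                f"grouping {self.name!r} must use exactly groups 1, 2, 3"
            )

    def as_array(self) -> np.ndarray:
        """Group id per residue in AMINO_ACIDS order."""
        return np.array([self.group_of[aa] for aa in AMINO_ACIDS], dtype=np.intp)


_AA_ORDER_SET = frozenset(AMINO_ACIDS)


def _grouping(name: str, g1: str, g2: str, g3: str) -> CtdGrouping:
    mapping = {aa: 1 for aa in g1}
    mapping.update({aa: 2 for aa in g2})
    mapping.update({aa: 3 for aa in g3})
    return CtdGrouping(name=name, group_of=mapping)


# Dubchak's seven attributes, each a 3-group partition of the alphabet.
DEFAULT_CTD_GROUPINGS: tuple[CtdGrouping, ...] = (
    _grouping("hydrophobicity", "RKEDQN", "GASTPHY", "CLVIMFW"),
    _grouping("vdw_volume", "GASTPDC", "NVEQIL", "MHKFRYW"),
    _grouping("polarity", "LIFWCMVY", "PATGS", "HQRKNED"),
    _grouping("polarizability", "GASDT", "CPNVEQIL", "KMHFRYW"),
    _grouping("charge", "KR", "ANCQGHILMFPSTWYV", "DE"),
    _grouping("secondary_structure", "EALMQKRH", "VIYCWFT", "GNPSD"),
    _grouping("solvent_accessibility", "ALFCGIVW", "RKQEND", "MPSTHY"),
)

_CTD_PERCENTILES = (0.0, 0.25, 0.50, 0.75, 1.0)


def ctd_feature_names(groupings: Sequence[CtdGrouping]) -> list[str]:
    names: list[str] = []
    for grp in groupings:
        names += [f"{grp.name}.C{g}" for g in (1, 2, 3)]
        names += [f"{grp.name}.T{g}{h}" for g, h in combinations((1, 2, 3), 2)]
        for g in (1, 2, 3):
            names += [
                f"{grp.name}.D{g}.{int(p * 100)}" for p in _CTD_PERCENTILES
            ]
    return names


def encode_ctd(
    record: ProteinRecord,
    groupings: Sequence[CtdGrouping] = DEFAULT_CTD_GROUPINGS,
) -> np.ndarray:
    """Composition, transition and distribution blocks per grouping.

    Per grouping: 3 composition fractions; 3 transition frequencies (one
    per unordered group pair, adjacent positions, divided by L-1); 15
    distribution values (first / 25% / 50% / 75% / last occurrence position
    of each group, as percent of chain length; absent groups contribute 0).
    """
    if record.length < 2:
        raise SequenceTooShortError(
            f"CTD needs L >= 2, got L={record.length} for {record.id!r}"
        )
    idx = _seq_indices(record)
    L = record.length
    out: list[float] = []
    for grp in groupings:
        g = grp.as_array()[idx]  # group id per position
        # composition
        comp = [float(np.sum(g == k)) / L for k in (1, 2, 3)]
        out += comp
        # transition: adjacent unordered pairs
        a, b = g[:-1], g[1:]
        for p, q in combinations((1, 2, 3), 2):
            n_trans = int(np.sum(((a == p) & (b == q)) | ((a == q) & (b == p))))
            out.append(n_trans / (L - 1))
        # distribution
        for k in (1, 2, 3):
            positions = np.flatnonzero(g == k) + 1  # 1-based
            if positions.size == 0:
                out += [0.0] * len(_CTD_PERCENTILES)
                continue
            n = positions.size
            for frac in _CTD_PERCENTILES:
                rank = max(int(np.ceil(frac * n)), 1)
                out.append(100.0 * positions[rank - 1] / L)
    return np.array(out, dtype=float)


# ---------------------------------------------------------------------------
# AAindex / ACF
# ---------------------------------------------------------------------------

# Residue order used by AAindex1 "I" blocks (two rows of ten).
_AAINDEX_ROW1 = "ARNDCQEGHI"
_AAINDEX_ROW2 = "LKMFPSTWYV"


@dataclass(frozen=True)
class AAIndexTable:
    """Complete-valued physicochemical index vectors, one row per index.

    ``values`` has shape (M, 20) in AMINO_ACIDS order; entries with any
    missing residue value were excluded at load time (``n_excluded``).
    """

    ids: tuple[str, ...]
    values: np.ndarray
    n_excluded: int = 0

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape[1] != 20:
            raise ValueError(f"values must be (M, 20), got {vals.shape}")
        if vals.shape[0] != len(self.ids):
            raise ValueError("ids and values disagree on M")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("index ids must be unique")
        if not np.isfinite(vals).all():
            raise ValueError("retained entries must have 20 finite values")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def standardized(self) -> np.ndarray:
        """Per-index zero-mean unit-sd values (population sd over 20 residues)."""
        mean = self.values.mean(axis=1, keepdims=True)
        sd = self.values.std(axis=1, keepdims=True)
        return (self.values - mean) / sd

    @property
    def snapshot_id(self) -> str:
        h = hashlib.sha256()
        h.update(",".join(self.ids).encode())
        h.update(np.ascontiguousarray(self.values).tobytes())
        return h.hexdigest()[:16]

    def subset(self, ids: Sequence[str]) -> "AAIndexTable":
        pos = {iid: i for i, iid in enumerate(self.ids)}
        rows = [pos[iid] for iid in ids]
        return AAIndexTable(ids=tuple(ids), values=self.values[rows])


def _parse_aaindex_blocks(text: str):
    """Yield (id, 20 raw tokens in AAindex row order) per '//'-terminated block."""
    block_id = None
    tokens: list[str] = []
    reading_values = False
    for line in text.splitlines():
        if line.startswith("//"):
            if block_id is not None:
                yield block_id, tokens
            block_id, tokens, reading_values = None, [], False
            continue
        if line.startswith("H"):
            block_id = line[1:].strip().split()[0]
            continue
        if line.startswith("I"):
            reading_values = True
            continue
        if reading_values and line.startswith((" ", "\t")):
            tokens += line.split()
        elif reading_values:
            reading_values = False
    if block_id is not None:
        yield block_id, tokens


def load_aaindex(path: str | Path | None = None) -> AAIndexTable:
    """Parse an AAindex1 flat file; defaults to the packaged snapshot.

    Entries with any missing ("NA") residue value are excluded and counted.
    """
    if path is None:
        text = (
            resources.files("protclass.data").joinpath("aaindex1.txt").read_text()
        )
    else:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(path)
        text = path.read_text()

    aaindex_order = _AAINDEX_ROW1 + _AAINDEX_ROW2
    reorder = [aaindex_order.index(aa) for aa in AMINO_ACIDS]
    ids: list[str] = []
    rows: list[np.ndarray] = []
    n_excluded = 0
    for block_id, tokens in _parse_aaindex_blocks(text):
        if len(tokens) != 20:
            raise ValueError(
                f"malformed AAindex entry {block_id!r}: "
                f"expected 20 values, found {len(tokens)}"
            )
        vals = np.array(
            [np.nan if t.upper() == "NA" else float(t) for t in tokens]
        )
        if np.isnan(vals).any():
            n_excluded += 1
            continue
        ids.append(block_id)
        rows.append(vals[reorder])
    if not rows:
        raise ValueError("no complete AAindex entries found")
    if n_excluded:
        logger.info("load_aaindex: excluded %d incomplete entr(ies)", n_excluded)
    return AAIndexTable(ids=tuple(ids), values=np.stack(rows), n_excluded=n_excluded)


def acf_feature_names(table: AAIndexTable, order: int) -> list[str]:
    return [f"{iid}.lag{d}" for iid in table.ids for d in range(1, order + 1)]


def encode_acf(record: ProteinRecord, table: AAIndexTable, order: int = 1) -> np.ndarray:
    """Lagged autocorrelations of standardized index values along the chain.

    value(m, d) = (1/(L-d)) * sum_i z_m(R_i) * z_m(R_{i+d}) for lag d in
    1..order; output is index-major then lag, length M * order.
    """
    if order < 1:
        raise ValueError(f"order must be >= 1, got {order}")
    if len(table) == 0:
        raise ValueError("empty AAindex table")
    if record.length < order + 1:
        raise SequenceTooShortError(
            f"ACF with order {order} needs L >= {order + 1}, "
            f"got L={record.length} for {record.id!r}"
        )
    idx = _seq_indices(record)
    z = table.standardized[:, idx]  # (M, L)
    per_lag = [
        (z[:, :-d] * z[:, d:]).mean(axis=1) for d in range(1, order + 1)
    ]  # each (M,)
    return np.stack(per_lag, axis=1).ravel()  # index-major, then lag


# ---------------------------------------------------------------------------
# composition summary (per-class mean AAC)
# ---------------------------------------------------------------------------

def composition_summary(
    dataset: LabeledDataset, by: Mapping[str, object] | Sequence[object]
) -> dict[object, np.ndarray]:
    """Arithmetic mean AAC vector per group.

    ``by`` maps record id -> group key, or is a per-record key sequence.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if isinstance(by, Mapping):
        keys = [by[r.id] for r in dataset.records]
    else:
        keys = list(by)
        if len(keys) != len(dataset):
            raise ValueError("one group key per record required")
    groups: dict[object, list[np.ndarray]] = {}
    for rec, key in zip(dataset.records, keys):
        groups.setdefault(key, []).append(encode_aac(rec))
    return {key: np.mean(vecs, axis=0) for key, vecs in groups.items()}


# ---------------------------------------------------------------------------
# batch encoding / FeatureMatrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureMatrix:
    """Named, ordered descriptor values for a batch of sequences."""

    scheme: str
    feature_names: tuple[str, ...]
    ids: tuple[str, ...]
    values: np.ndarray
    fingerprint: str

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2 or vals.shape != (len(self.ids), len(self.feature_names)):
            raise ValueError(
                f"values shape {vals.shape} does not match "
                f"{len(self.ids)} ids x {len(self.feature_names)} features"
            )
        object.__setattr__(self, "values", vals)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def __len__(self) -> int:
        return len(self.ids)

    def subset(self, indices: Sequence[int] | np.ndarray) -> "FeatureMatrix":
        idx = np.asarray(indices, dtype=int)
        return FeatureMatrix(
            scheme=self.scheme,
            feature_names=self.feature_names,
            ids=tuple(self.ids[i] for i in idx),
            values=self.values[idx],
            fingerprint=self.fingerprint,
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.values, index=list(self.ids), columns=list(self.feature_names)
        ).rename_axis("sequence_id")


class Encoder:
    """A configured descriptor scheme: per-record and batch encoding.

    The fingerprint hashes the scheme, its parameters and the feature name
    list, so a model trained on one configuration refuses features from
    another.
    """

    def __init__(
        self,
        scheme: str,
        feature_names: Sequence[str],
        min_length: int,
        param_token: str,
    ):
        self.scheme = scheme
        self.feature_names = tuple(feature_names)
        self.min_length = min_length
        self._param_token = param_token

    @property
    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(self.scheme.encode())
        h.update(self._param_token.encode())
        h.update("|".join(self.feature_names).encode())
        return h.hexdigest()[:16]

    def encode(self, record: ProteinRecord) -> np.ndarray:
        raise NotImplementedError

    def transform(self, records: Iterable[ProteinRecord]) -> FeatureMatrix:
        records = list(records)
        values = (
            np.stack([self.encode(r) for r in records])
            if records
            else np.empty((0, len(self.feature_names)))
        )
        return FeatureMatrix(
            scheme=self.scheme,
            feature_names=self.feature_names,
            ids=tuple(r.id for r in records),
            values=values,
            fingerprint=self.fingerprint,
        )


class AacEncoder(Encoder):
    def __init__(self):
        super().__init__("AAC", aac_feature_names(), 1, "")

    def encode(self, record: ProteinRecord) -> np.ndarray:
        return encode_aac(record)


class DpcEncoder(Encoder):
    def __init__(self):
        super().__init__("DPC", dpc_feature_names(), 2, "")

    def encode(self, record: ProteinRecord) -> np.ndarray:
        return encode_dpc(record)


class PaacEncoder(Encoder):
    def __init__(self, params: PaacParams | None = None):
        self.params = params or PaacParams()
        token = (
            f"lam={self.params.lam};w={self.params.weight!r};"
            f"props={hashlib.sha256(self.params.properties.tobytes()).hexdigest()[:8]}"
        )
        super().__init__(
            "PAAC", paac_feature_names(self.params), self.params.lam + 1, token
        )

    def encode(self, record: ProteinRecord) -> np.ndarray:
        return encode_paac(record, self.params)


class CtdEncoder(Encoder):
    def __init__(self, groupings: Sequence[CtdGrouping] = DEFAULT_CTD_GROUPINGS):
        self.groupings = tuple(groupings)
        token = ";".join(
            f"{g.name}:" + "".join(str(g.group_of[aa]) for aa in AMINO_ACIDS)
            for g in self.groupings
        )
        super().__init__("CTD", ctd_feature_names(self.groupings), 2, token)

    def encode(self, record: ProteinRecord) -> np.ndarray:
        return encode_ctd(record, self.groupings)


class AcfEncoder(Encoder):
    def __init__(self, table: AAIndexTable | None = None, order: int = 1):
        self.table = table if table is not None else load_aaindex()
        self.order = order
        token = f"order={order};snapshot={self.table.snapshot_id}"
        super().__init__(
            "ACF", acf_feature_names(self.table, order), order + 1, token
        )

    def encode(self, record: ProteinRecord) -> np.ndarray:
        return encode_acf(record, self.table, self.order)


def get_encoder(
    scheme: str,
    *,
    paac_params: PaacParams | None = None,
    ctd_groupings: Sequence[CtdGrouping] | None = None,
    aaindex: AAIndexTable | None = None,
    acf_order: int = 1,
) -> Encoder:
    """Build a configured encoder for one of the five schemes."""
    scheme = scheme.upper()
    if scheme == "AAC":
        return AacEncoder()
    if scheme == "DPC":
        return DpcEncoder()
    if scheme == "PAAC":
        return PaacEncoder(paac_params)
    if scheme == "CTD":
        return CtdEncoder(ctd_groupings or DEFAULT_CTD_GROUPINGS)
    if scheme == "ACF":
        return AcfEncoder(aaindex, acf_order)
    raise ValueError(f"unknown scheme {scheme!r}; choose one of {SCHEMES}")
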