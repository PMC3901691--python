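"""The 1486-descriptor feature space and its encoder.

A protein chain is described by thirteen descriptor families drawn from four
categories:

* secondary-structure content (``Con_SS_y``), 3 descriptors;
* average relative solvent accessibility over residue subsets
  (``AveRSA_Res_x``, ``AveRSA_SS_y``, ``AveRSA_Res_x_SS_y``), 20+3+60;
* amino-acid composition, plain and conditioned on SS state or
  buried/exposed status at five RSA cutoffs, plus dipeptide composition
  (``AAC_Res_x``, ``AAC_Res_x_SS_y``, ``AAC_Res_x_Ex_h``, ``AAC_Res_x_Bu_h``,
  ``DIC_Res_xx'``), 20+60+100+100+400;
* PSSM-score statistics over the logistic-normalized profile: column
  averages, residue-conditioned column averages, nearest-rank column
  percentiles and lagged auto-correlation coefficients
  (``AvePscore_AA_x``, ``AvePscore_AA_x_Res_x'``, ``Pscore_AA_x_P_t``,
  ``AutoCC_AA_x_Lag_m``), 20+400+100+200.

Family sizes sum to 1486.  Residue types run over the canonical alphabetical
AA order, SS states over (C, H, E), RSA cutoffs h over {0.1..0.5}, percentile
thresholds t over {0, 25, 50, 75, 100} and lags m over {1..10}.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .io import AA_ALPHABET, FeatureMatrix, ProteinRecord, PSSMatrix, StructuralProfile

SS_ORDER = "CHE"
RSA_CUTOFFS = (0.1, 0.2, 0.3, 0.4, 0.5)
PERCENTILE_THRESHOLDS = (0, 25, 50, 75, 100)
LAGS = tuple(range(1, 11))

CATEGORY_SS = "SS_content"
CATEGORY_AVERSA = "AveRSA"
CATEGORY_AAC = "AAC"
CATEGORY_PSSM = "PSSM"

N_DESCRIPTORS = 1486

#: (family id, category, printed family size), in feature-table order.
FAMILY_TABLE = (
    ("Con_SS", CATEGORY_SS, 3),
    ("AveRSA_Res", CATEGORY_AVERSA, 20),
    ("AveRSA_SS", CATEGORY_AVERSA, 3),
    ("AveRSA_Res_SS", CATEGORY_AVERSA, 60),
    ("AAC_Res", CATEGORY_AAC, 20),
    ("AAC_Res_SS", CATEGORY_AAC, 60),
    ("AAC_Res_Ex", CATEGORY_AAC, 100),
    ("AAC_Res_Bu", CATEGORY_AAC, 100),
    ("DIC_Res", CATEGORY_AAC, 400),
    ("AvePscore_AA", CATEGORY_PSSM, 20),
    ("AvePscore_AA_Res", CATEGORY_PSSM, 400),
    ("Pscore_P", CATEGORY_PSSM, 100),
    ("AutoCC_Lag", CATEGORY_PSSM, 200),
)


@dataclass(frozen=True)
class FeatureDescriptor:
    name: str
    family: str
    category: str
    params: tuple = ()


@dataclass
class FeatureSpace:
    """Ordered, named registry of all descriptors."""

    descriptors: list[FeatureDescriptor]
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.index = {d.name: i for i, d in enumerate(self.descriptors)}
        if len(self.index) != len(self.descriptors):
            raise ValueError("duplicate descriptor names in feature space")

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.descriptors]

    def __len__(self) -> int:
        return len(self.descriptors)

    def family_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {}
        for d in self.descriptors:
            sizes[d.family] = sizes.get(d.family, 0) + 1
        return sizes


def _fmt_h(h: float) -> str:
    return f"{h:g}"


def enumerate_feature_space() -> FeatureSpace:
    """Enumerate all 1486 descriptors in deterministic family/parameter order."""
    desc: list[FeatureDescriptor] = []

    def add(name, family, category, *params):
        desc.append(FeatureDescriptor(name, family, category, tuple(params)))

    for y in SS_ORDER:
        add(f"Con_SS_{y}", "Con_SS", CATEGORY_SS, y)
    for x in AA_ALPHABET:
        add(f"AveRSA_Res_{x}", "AveRSA_Res", CATEGORY_AVERSA, x)
    for y in SS_ORDER:
        add(f"AveRSA_SS_{y}", "AveRSA_SS", CATEGORY_AVERSA, y)
    for x in AA_ALPHABET:
        for y in SS_ORDER:
            add(f"AveRSA_Res_{x}_SS_{y}", "AveRSA_Res_SS", CATEGORY_AVERSA, x, y)
    for x in AA_ALPHABET:
        add(f"AAC_Res_{x}", "AAC_Res", CATEGORY_AAC, x)
    for x in AA_ALPHABET:
        for y in SS_ORDER:
            add(f"AAC_Res_{x}_SS_{y}", "AAC_Res_SS", CATEGORY_AAC, x, y)
    for x in AA_ALPHABET:
        for h in RSA_CUTOFFS:
            add(f"AAC_Res_{x}_Ex_{_fmt_h(h)}", "AAC_Res_Ex", CATEGORY_AAC, x, h)
    for x in AA_ALPHABET:
        for h in RSA_CUTOFFS:
            add(f"AAC_Res_{x}_Bu_{_fmt_h(h)}", "AAC_Res_Bu", CATEGORY_AAC, x, h)
    for x in AA_ALPHABET:
        for x2 in AA_ALPHABET:
            add(f"DIC_Res_{x}{x2}", "DIC_Res", CATEGORY_AAC, x, x2)
    for x in AA_ALPHABET:
        add(f"AvePscore_AA_{x}", "AvePscore_AA", CATEGORY_PSSM, x)
    for x in AA_ALPHABET:
        for x2 in AA_ALPHABET:
            add(f"AvePscore_AA_{x}_Res_{x2}", "AvePscore_AA_Res", CATEGORY_PSSM, x, x2)
    for x in AA_ALPHABET:
        for t in PERCENTILE_THRESHOLDS:
            add(f"Pscore_AA_{x}_P_{t}", "Pscore_P", CATEGORY_PSSM, x, t)
    for x in AA_ALPHABET:
        for m in LAGS:
            add(f"AutoCC_AA_{x}_Lag_{m}", "AutoCC_Lag", CATEGORY_PSSM, x, m)

    space = FeatureSpace(desc)
    assert len(space) == N_DESCRIPTORS
    return space


# ---------------------------------------------------------------------------
# descriptor-name grammar

_NAME_PATTERNS = (
    (re.compile(r"^Con_SS_([CHE])$"), "Con_SS", CATEGORY_SS),
    (re.compile(r"^AveRSA_Res_([A-Z])_SS_([CHE])$"), "AveRSA_Res_SS", CATEGORY_AVERSA),
    (re.compile(r"^AveRSA_Res_([A-Z])$"), "AveRSA_Res", CATEGORY_AVERSA),
    (re.compile(r"^AveRSA_SS_([CHE])$"), "AveRSA_SS", CATEGORY_AVERSA),
    (re.compile(r"^AAC_Res_([A-Z])_SS_([CHE])$"), "AAC_Res_SS", CATEGORY_AAC),
    (re.compile(r"^AAC_Res_([A-Z])_Ex_(0\.[1-5])$"), "AAC_Res_Ex", CATEGORY_AAC),
    (re.compile(r"^AAC_Res_([A-Z])_Bu_(0\.[1-5])$"), "AAC_Res_Bu", CATEGORY_AAC),
    (re.compile(r"^AAC_Res_([A-Z])$"), "AAC_Res", CATEGORY_AAC),
    (re.compile(r"^DIC_Res_([A-Z])([A-Z])$"), "DIC_Res", CATEGORY_AAC),
    (re.compile(r"^AvePscore_AA_([A-Z])_Res_([A-Z])$"), "AvePscore_AA_Res", CATEGORY_PSSM),
    (re.compile(r"^AvePscore_AA_([A-Z])$"), "AvePscore_AA", CATEGORY_PSSM),
    (re.compile(r"^Pscore_AA_([A-Z])_P_(0|25|50|75|100)$"), "Pscore_P", CATEGORY_PSSM),
    (re.compile(r"^AutoCC_AA_([A-Z])_Lag_(10|[1-9])$"), "AutoCC_Lag", CATEGORY_PSSM),
)


def normalize_descriptor_name(name: str) -> str:
    """Canonicalize a printed descriptor name.

    Published tables set parameter tokens in italics, which leaves stray
    spaces, doubled and trailing underscores when extracted as plain text;
    the dipeptide family also appears under the alias ``DIP``.  All are
    normalized here.
    """
    clean = re.sub(r"\s+", "", name)
    clean = re.sub(r"_+", "_", clean).strip("_")
    if clean.startswith("DIP_"):
        clean = "DIC_" + clean[4:]
    return clean


def parse_descriptor_name(name: str) -> FeatureDescriptor:
    """Parse a descriptor name (printed or canonical) via the naming grammar."""
    clean = normalize_descriptor_name(name)
    for pattern, family, category in _NAME_PATTERNS:
        m = pattern.match(clean)
        if m:
            return FeatureDescriptor(clean, family, category, m.groups())
    raise ValueError(f"unparseable descriptor name: {name!r}")


# ---------------------------------------------------------------------------
# family encoders


def normalize_pssm(raw: PSSMatrix) -> PSSMatrix:
    """Map raw log-odds scores through the standard logistic 1/(1+e^-s)."""
    if raw.normalized:
        return raw
    return PSSMatrix(
        protein_id=raw.protein_id, scores=expit(raw.scores), normalized=True
    )


def _aa_indices(sequence: str) -> np.ndarray:
    lut = {aa: i for i, aa in enumerate(AA_ALPHABET)}
    return np.fromiter((lut[c] for c in sequence), dtype=np.intp, count=len(sequence))


def encode_ss_content(profile: StructuralProfile) -> np.ndarray:
    """Fraction of residues in each SS state, order (C, H, E); sums to 1."""
    L = len(profile)
    return np.array([profile.ss.count(y) / L for y in SS_ORDER])


def encode_ave_rsa(record: ProteinRecord, profile: StructuralProfile) -> np.ndarray:
    """Mean RSA over residue subsets (by AA type, SS state, and both).

    83 values in space order; an empty subset contributes 0.
    """
    rsa = profile.rsa
    aa_idx = _aa_indices(record.sequence)
    ss_arr = np.frombuffer(profile.ss.encode(), dtype=np.uint8)
    out = []
    aa_masks = [aa_idx == i for i in range(20)]
    ss_masks = [ss_arr == ord(y) for y in SS_ORDER]
    for m in aa_masks:
        out.append(rsa[m].mean() if m.any() else 0.0)
    for m in ss_masks:
        out.append(rsa[m].mean() if m.any() else 0.0)
    for ma in aa_masks:
        for ms in ss_masks:
            m = ma & ms
            out.append(rsa[m].mean() if m.any() else 0.0)
    return np.asarray(out)


def encode_aac(record: ProteinRecord, profile: StructuralProfile) -> np.ndarray:
    """Composition families: AAC, SS-conditioned, exposed/buried, dipeptide.

    680 values in space order.  Exposure rule: RSA >= h is solvent exposed,
    otherwise buried; compositions are counts over L (dipeptides over L-1).
    """
    L = len(record)
    aa_idx = _aa_indices(record.sequence)
    ss_arr = np.frombuffer(profile.ss.encode(), dtype=np.uint8)
    rsa = profile.rsa

    aac = np.bincount(aa_idx, minlength=20) / L

    aac_ss = np.zeros((20, 3))
    for j, y in enumerate(SS_ORDER):
        ms = ss_arr == ord(y)
        aac_ss[:, j] = np.bincount(aa_idx[ms], minlength=20) / L

    aac_ex = np.zeros((20, len(RSA_CUTOFFS)))
    for j, h in enumerate(RSA_CUTOFFS):
        me = rsa >= h
        aac_ex[:, j] = np.bincount(aa_idx[me], minlength=20) / L
    aac_bu = aac[:, None] - aac_ex  # buried complement at each cutoff

    if L > 1:
        pair_idx = aa_idx[:-1] * 20 + aa_idx[1:]
        dic = np.bincount(pair_idx, minlength=400) / (L - 1)
    else:
        warnings.warn(
            f"record {record.id!r}: length-1 sequence, dipeptide family set to 0",
            stacklevel=2,
        )
        dic = np.zeros(400)

    return np.concatenate([aac, aac_ss.ravel(), aac_ex.ravel(), aac_bu.ravel(), dic])


def encode_pssm_averages(record: ProteinRecord, norm: PSSMatrix) -> np.ndarray:
    """Column means of the normalized PSSM, plain and residue-conditioned.

    420 values: AvePscore_AA_x (20) then AvePscore_AA_x_Res_x' (20 x 20,
    column x outer, residue type x' inner).  Empty residue subsets give 0.
    """
    if not norm.normalized:
        raise ValueError("encode_pssm_averages expects a logistic-normalized PSSM")
    S = norm.scores
    ave = S.mean(axis=0)
    aa_idx = _aa_indices(record.sequence)
    cond = np.zeros((20, 20))  # [column x, residue x']
    for x2 in range(20):
        m = aa_idx == x2
        if m.any():
            cond[:, x2] = S[m].mean(axis=0)
    return np.concatenate([ave, cond.ravel()])


def encode_pssm_percentiles(norm: PSSMatrix) -> np.ndarray:
    """Nearest-rank percentiles of each normalized column at t in {0,25,50,75,100}.

    t=0 is the column minimum and t=100 the maximum; values are
    non-decreasing in t.  100 values (column x outer, t inner).
    """
    if not norm.normalized:
        raise ValueError("encode_pssm_percentiles expects a logistic-normalized PSSM")
    S = np.sort(norm.scores, axis=0)
    L = S.shape[0]
    out = np.zeros((20, len(PERCENTILE_THRESHOLDS)))
    for j, t in enumerate(PERCENTILE_THRESHOLDS):
        if t == 0:
            k = 0
        else:
            k = int(np.ceil(t / 100 * L)) - 1  # nearest-rank
        out[:, j] = S[k, :]
    return out.ravel()


def encode_autocc(norm: PSSMatrix) -> np.ndarray:
    """Lagged auto-correlation of each normalized column series.

    For column series S_1..S_L with mean S-bar, the coefficient at lag m is

        r_m = sum_{i=1}^{L-m} (S_i - S-bar)(S_{i+m} - S-bar)
              / sum_{i=1}^{L} (S_i - S-bar)^2,

    which is bounded in [-1, 1].  Zero-variance columns give 0; lags >= L
    give 0 with a warning.  200 values (column x outer, lag m inner).
    """
    if not norm.normalized:
        raise ValueError("encode_autocc expects a logistic-normalized PSSM")
    S = norm.scores
    L = S.shape[0]
    centered = S - S.mean(axis=0, keepdims=True)
    denom = (centered**2).sum(axis=0)
    out = np.zeros((20, len(LAGS)))
    for j, m in enumerate(LAGS):
        if L <= m:
            warnings.warn(
                f"PSSM {norm.protein_id!r}: length {L} <= lag {m}, AutoCC set to 0",
                stacklevel=2,
            )
            continue
        num = (centered[:-m] * centered[m:]).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
        out[:, j] = r
    return out.ravel()


def encode_all(
    record: ProteinRecord,
    pssm: PSSMatrix,
    profile: StructuralProfile,
    space: FeatureSpace | None = None,
) -> np.ndarray:
    """Encode one protein into the full 1486-value descriptor vector.

    The raw PSSM is logistic-normalized once, then every PSSM-based family
    is computed from the normalized matrix.
    """
    L = len(record)
    if len(pssm) != L or len(profile) != L:
        raise ValueError(
            f"record {record.id!r}: inconsistent lengths (sequence {L}, "
            f"PSSM {len(pssm)}, profile {len(profile)})"
        )
    norm = normalize_pssm(pssm)
    vec = np.concatenate(
        [
            encode_ss_content(profile),
            encode_ave_rsa(record, profile),
            encode_aac(record, profile),
            encode_pssm_averages(record, norm),
            encode_pssm_percentiles(norm),
            encode_autocc(norm),
        ]
    )
    if space is not None and len(vec) != len(space):
        raise ValueError("encoded vector does not align with the feature space")
    assert np.all(np.isfinite(vec))
    return vec


class FeatureEncoder:
    """Stateless transformer from (record, PSSM, profile) triples to a
    named feature matrix."""

    def __init__(self) -> None:
        self.space_ = enumerate_feature_space()

    def encode(
        self, record: ProteinRecord, pssm: PSSMatrix, profile: StructuralProfile
    ) -> np.ndarray:
        return encode_all(record, pssm, profile, self.space_)

    def encode_dataset(
        self,
        records: list[ProteinRecord],
        pssms: dict[str, PSSMatrix],
        profiles: dict[str, StructuralProfile],
    ) -> FeatureMatrix:
        rows = []
        labels = []
        has_labels = all(r.label != "unknown" for r in records)
        for rec in records:
            if rec.id not in pssms:
                raise KeyError(f"no PSSM provided for protein {rec.id!r}")
            if rec.id not in profiles:
                raise KeyError(f"no structural profile provided for protein {rec.id!r}")
            rows.append(self.encode(rec, pssms[rec.id], profiles[rec.id]))
            labels.append(1 if rec.label == "positive" else 0)
        df = pd.DataFrame(
            np.asarray(rows), index=[r.id for r in records], columns=self.space_.names
        )
        return FeatureMatrix(
            values=df, labels=pd.Series(labels, index=df.index) if has_labels else None
        )
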