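"""Synthetic labeled datasets for end-to-end testing without downloads.

Every input kind the pipeline consumes is emulated: AA sequences drawn from
a background composition, integer PSSM scores from a discretized normal
(mean 0, sd 3, clipped to [-10, 10]), 3-state secondary structure from a
first-order Markov chain and RSA from a Beta distribution.  Class-dependent
*effects* shift the positive class's generating parameters so that a named
descriptor's expected class difference equals a requested effect size,
expressed in units of the descriptor's baseline between-protein standard
deviation.  The shift is calibrated by Monte-Carlo bisection on the
generating parameter and the realized standardized difference is recorded
in the truth annotation.

Supported effect channels (one generating parameter each):

* ``AvePscore_AA_x`` / ``Pscore_AA_x_P_t`` — mean shift of raw PSSM column x;
* ``AAC_Res_x`` — extra probability mass on AA type x;
* ``Con_SS_y`` — tilt of the SS chain's stationary distribution toward y;
* ``AveRSA_Res_x`` — shift of the RSA Beta mean for residues of type x.

None of this emulates real evolutionary profiles or DNA-binding biology;
it exists so that contracts and recovery behaviour are testable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import expit

from . import io as _io
from .features import (
    FeatureEncoder,
    encode_all,
    enumerate_feature_space,
    parse_descriptor_name,
)
from .io import (
    AA_ALPHABET,
    FeatureMatrix,
    ProteinRecord,
    PSSMatrix,
    StructuralProfile,
    write_fasta,
    write_manifest,
    write_pssm,
    write_structural_profile,
)

SS_ORDER = "CHE"
PSSM_SD = 3.0
PSSM_CLIP = 10
RSA_CONCENTRATION = 4.0
SS_STAY_PROB = 0.8

SUPPORTED_EFFECT_FAMILIES = ("AvePscore_AA", "Pscore_P", "AAC_Res", "Con_SS", "AveRSA_Res")


@dataclass(frozen=True)
class Effect:
    """A class-dependent shift on one descriptor.

    ``size`` is the requested positive-minus-negative difference in
    baseline-standard-deviation units; negative sizes shift downward.
    """

    descriptor: str
    size: float


@dataclass
class EffectConfig:
    seed: int
    n_pos: int = 100
    n_neg: int = 100
    length_range: tuple[int, int] = (60, 120)
    effects: tuple[Effect, ...] = ()

    def __post_init__(self) -> None:
        lo, hi = self.length_range
        if lo < 11:
            raise ValueError("minimum length must be >= 11 so all lags 1..10 exist")
        if hi < lo:
            raise ValueError("length_range must be (min, max) with max >= min")
        self.effects = tuple(
            e if isinstance(e, Effect) else Effect(*e) for e in self.effects
        )
        for e in self.effects:
            if not np.isfinite(e.size):
                raise ValueError(f"effect size for {e.descriptor!r} must be finite")


@dataclass
class GenParams:
    """Generating parameters for one class."""

    aa_probs: np.ndarray
    pssm_shift: np.ndarray  # per-column raw-score mean
    ss_fresh: np.ndarray  # stationary distribution of the SS chain
    rsa_mean: np.ndarray  # per-AA-type Beta mean

    @classmethod
    def background(cls) -> "GenParams":
        return cls(
            aa_probs=np.full(20, 1 / 20),
            pssm_shift=np.zeros(20),
            ss_fresh=np.full(3, 1 / 3),
            rsa_mean=np.full(20, 0.5),
        )


@dataclass
class SyntheticDataset:
    records: list[ProteinRecord]
    pssms: dict[str, PSSMatrix]
    profiles: dict[str, StructuralProfile]
    truth: dict

    def encode(self) -> FeatureMatrix:
        return FeatureEncoder().encode_dataset(self.records, self.pssms, self.profiles)

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        (out / "pssm").mkdir(parents=True, exist_ok=True)
        (out / "profiles").mkdir(parents=True, exist_ok=True)
        write_fasta(self.records, out / "sequences.fasta")
        write_manifest(self.records, out / "manifest.tsv")
        for rec in self.records:
            write_pssm(self.pssms[rec.id], rec.sequence, out / "pssm" / f"{rec.id}.pssm")
            write_structural_profile(
                self.profiles[rec.id], rec.sequence, out / "profiles" / f"{rec.id}.ss"
            )
        _io.write_json(self.truth, out / "truth.json")


# ---------------------------------------------------------------------------
# per-protein samplers


def _sample_length(rng: np.random.Generator, length_range) -> int:
    lo, hi = length_range
    return int(rng.integers(lo, hi + 1))


def _sample_sequence(rng, L: int, aa_probs) -> np.ndarray:
    return rng.choice(20, size=L, p=aa_probs)


def _sample_pssm_column(rng, L: int, shift: float) -> np.ndarray:
    raw = np.rint(rng.normal(loc=shift, scale=PSSM_SD, size=L))
    return np.clip(raw, -PSSM_CLIP, PSSM_CLIP)


def _sample_pssm(rng, L: int, shifts) -> np.ndarray:
    raw = np.rint(rng.normal(loc=shifts[None, :], scale=PSSM_SD, size=(L, 20)))
    return np.clip(raw, -PSSM_CLIP, PSSM_CLIP)


def _sample_ss(rng, L: int, fresh) -> np.ndarray:
    states = np.empty(L, dtype=np.intp)
    states[0] = rng.choice(3, p=fresh)
    stay = rng.random(L) < SS_STAY_PROB
    fresh_draws = rng.choice(3, size=L, p=fresh)
    for i in range(1, L):
        states[i] = states[i - 1] if stay[i] else fresh_draws[i]
    return states


def _sample_rsa(rng, aa_idx, rsa_mean) -> np.ndarray:
    mu = rsa_mean[aa_idx]
    a = mu * RSA_CONCENTRATION
    b = (1 - mu) * RSA_CONCENTRATION
    return rng.beta(a, b)


# ---------------------------------------------------------------------------
# effect calibration

_N_CAL = 400


def _descriptor_samples(
    family: str, params: tuple, gp: GenParams, seed: int, length_range, n: int = _N_CAL
) -> np.ndarray:
    """Monte-Carlo sample of one descriptor's per-protein values under ``gp``.

    Only the generative channel the descriptor depends on is simulated.
    The fixed ``seed`` gives common random numbers across calibration calls
    so the bisection objective is smooth in the shifted parameter.
    """
    rng = np.random.default_rng(seed)
    out = np.empty(n)
    if family in ("AvePscore_AA", "Pscore_P"):
        x = AA_ALPHABET.index(params[0])
        for i in range(n):
            L = _sample_length(rng, length_range)
            col = expit(_sample_pssm_column(rng, L, gp.pssm_shift[x]))
            if family == "AvePscore_AA":
                out[i] = col.mean()
            else:
                t = int(params[1])
                s = np.sort(col)
                k = 0 if t == 0 else int(np.ceil(t / 100 * L)) - 1
                out[i] = s[k]
    elif family == "AAC_Res":
        x = AA_ALPHABET.index(params[0])
        for i in range(n):
            L = _sample_length(rng, length_range)
            out[i] = rng.binomial(L, gp.aa_probs[x]) / L
    elif family == "Con_SS":
        y = SS_ORDER.index(params[0])
        for i in range(n):
            L = _sample_length(rng, length_range)
            out[i] = np.mean(_sample_ss(rng, L, gp.ss_fresh) == y)
    elif family == "AveRSA_Res":
        x = AA_ALPHABET.index(params[0])
        for i in range(n):
            L = _sample_length(rng, length_range)
            k = rng.binomial(L, gp.aa_probs[x])
            if k == 0:
                out[i] = 0.0
            else:
                mu = gp.rsa_mean[x]
                out[i] = rng.beta(
                    mu * RSA_CONCENTRATION, (1 - mu) * RSA_CONCENTRATION, size=k
                ).mean()
    else:  # pragma: no cover - guarded by caller
        raise ValueError(f"unsupported effect family {family!r}")
    return out


def _apply_delta(gp: GenParams, family: str, params: tuple, delta: float) -> GenParams:
    new = GenParams(
        aa_probs=gp.aa_probs.copy(),
        pssm_shift=gp.pssm_shift.copy(),
        ss_fresh=gp.ss_fresh.copy(),
        rsa_mean=gp.rsa_mean.copy(),
    )
    if family in ("AvePscore_AA", "Pscore_P"):
        new.pssm_shift[AA_ALPHABET.index(params[0])] += delta
    elif family == "AAC_Res":
        x = AA_ALPHABET.index(params[0])
        p = new.aa_probs
        target = np.clip(p[x] + delta, 1e-4, 0.95)
        scale = (1 - target) / (1 - p[x])
        p *= scale
        p[x] = target
        p /= p.sum()
    elif family == "Con_SS":
        y = SS_ORDER.index(params[0])
        f = new.ss_fresh
        target = np.clip(f[y] + delta, 1e-4, 0.98)
        scale = (1 - target) / (1 - f[y])
        f *= scale
        f[y] = target
        f /= f.sum()
    elif family == "AveRSA_Res":
        x = AA_ALPHABET.index(params[0])
        new.rsa_mean[x] = np.clip(new.rsa_mean[x] + delta, 0.02, 0.98)
    return new


_DELTA_RANGE = {
    "AvePscore_AA": (-8.0, 8.0),
    "Pscore_P": (-8.0, 8.0),
    "AAC_Res": (-0.9, 0.9),
    "Con_SS": (-0.9, 0.9),
    "AveRSA_Res": (-0.9, 0.9),
}


def _calibrate_effect(
    base: GenParams, effect: Effect, cal_seed: int, length_range
) -> tuple[float, str, tuple]:
    """Find the generating-parameter shift realizing ``effect.size``.

    Returns (delta, family, params).  Monotone bisection on the descriptor's
    Monte-Carlo mean, using common random numbers.
    """
    desc = parse_descriptor_name(effect.descriptor)
    if desc.family not in SUPPORTED_EFFECT_FAMILIES:
        raise ValueError(
            f"effects on family {desc.family!r} are not supported; supported "
            f"families: {SUPPORTED_EFFECT_FAMILIES}"
        )
    base_vals = _descriptor_samples(desc.family, desc.params, base, cal_seed, length_range)
    if base_vals.std(ddof=1) == 0:
        raise ValueError(f"descriptor {effect.descriptor!r} has zero baseline spread")

    def size_at(delta: float) -> float:
        """Standardized mean difference in pooled-std units at shift delta."""
        gp = _apply_delta(base, desc.family, desc.params, delta)
        vals = _descriptor_samples(desc.family, desc.params, gp, cal_seed, length_range)
        pooled = np.sqrt(0.5 * (vals.var(ddof=1) + base_vals.var(ddof=1)))
        return (vals.mean() - base_vals.mean()) / pooled

    lo, hi = _DELTA_RANGE[desc.family]
    # size_at is nondecreasing in delta for every supported channel
    if size_at(hi) < effect.size or size_at(lo) > effect.size:
        raise ValueError(
            f"requested effect {effect.size} on {effect.descriptor!r} is outside "
            "the generator's attainable range"
        )
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if size_at(mid) < effect.size:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi), desc.family, desc.params


# ---------------------------------------------------------------------------
# dataset generation


def _generate_protein(rng, pid: str, label: str, gp: GenParams, length_range):
    L = _sample_length(rng, length_range)
    aa_idx = _sample_sequence(rng, L, gp.aa_probs)
    seq = "".join(AA_ALPHABET[i] for i in aa_idx)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # short synthetic chains are intended
        rec = ProteinRecord(id=pid, sequence=seq, label=label)
    pssm = PSSMatrix(protein_id=pid, scores=_sample_pssm(rng, L, gp.pssm_shift))
    ss = "".join(SS_ORDER[s] for s in _sample_ss(rng, L, gp.ss_fresh))
    rsa = np.round(_sample_rsa(rng, aa_idx, gp.rsa_mean), 4)
    profile = StructuralProfile(protein_id=pid, ss=ss, rsa=rsa)
    return rec, pssm, profile


def generate_dataset(config: EffectConfig, out_dir: str | Path | None = None) -> SyntheticDataset:
    """Generate a labeled dataset under ``config``; optionally write files.

    Fully reproducible from ``config.seed``: the same config produces
    byte-identical files.  The truth annotation records, per effect, the
    calibrated parameter shift and the realized standardized descriptor
    difference between the classes.
    """
    ss_root = np.random.SeedSequence(config.seed)
    cal_seed, gen_seed = (int(s % 2**31) for s in ss_root.generate_state(2))

    base = GenParams.background()
    pos = GenParams.background()
    effect_log = []
    for eff in config.effects:
        delta, family, params = _calibrate_effect(base, eff, cal_seed, config.length_range)
        pos = _apply_delta(pos, family, params, delta)
        effect_log.append({"descriptor": eff.descriptor, "requested_size": eff.size,
                           "delta": delta})

    rng = np.random.default_rng(gen_seed)
    records, pssms, profiles = [], {}, {}
    for i in range(config.n_pos):
        rec, pssm, prof = _generate_protein(
            rng, f"pos{i + 1:04d}", _io.LABEL_POSITIVE, pos, config.length_range
        )
        records.append(rec)
        pssms[rec.id] = pssm
        profiles[rec.id] = prof
    for i in range(config.n_neg):
        rec, pssm, prof = _generate_protein(
            rng, f"neg{i + 1:04d}", _io.LABEL_NEGATIVE, base, config.length_range
        )
        records.append(rec)
        pssms[rec.id] = pssm
        profiles[rec.id] = prof

    # realized effect sizes, from the actual encoded descriptor values
    if effect_log:
        space = enumerate_feature_space()
        idx = {e["descriptor"]: space.index[
            parse_descriptor_name(e["descriptor"]).name] for e in effect_log}
        vals = {d: ([], []) for d in idx}
        for rec in records:
            vec = encode_all(rec, pssms[rec.id], profiles[rec.id])
            bucket = 0 if rec.label == _io.LABEL_POSITIVE else 1
            for d, j in idx.items():
                vals[d][bucket].append(vec[j])
        for entry in effect_log:
            a, b = (np.asarray(v) for v in vals[entry["descriptor"]])
            pooled = np.sqrt(0.5 * (a.var(ddof=1) + b.var(ddof=1)))
            entry["realized_size"] = float((a.mean() - b.mean()) / pooled) if pooled else 0.0

    truth = {
        "seed": config.seed,
        "n_pos": config.n_pos,
        "n_neg": config.n_neg,
        "length_range": list(config.length_range),
        "effects": effect_log,
    }
    ds = SyntheticDataset(records=records, pssms=pssms, profiles=profiles, truth=truth)
    if out_dir is not None:
        ds.write(out_dir)
    return ds


# ---------------------------------------------------------------------------
# the fixed worked example


def make_toy_worked_example() -> dict:
    """A 12-residue protein with hand-specified inputs and hand-computed
    descriptor values for the families with closed-form toy results.

    PSSM column A alternates raw scores +2/-2 (so its logistic-normalized
    series alternates around 0.5); all other columns are constant 0
    (normalized 0.5), making every AutoCC value for them exactly 0.
    """
    seq = "AACDAKEKAHHG"
    ss = "HHHHEEEECCCC"
    rsa = np.array([0.8, 0.1, 0.5, 0.3, 0.0, 1.0, 0.6, 0.2, 0.4, 0.9, 0.7, 0.05])
    L = len(seq)
    scores = np.zeros((L, 20))
    scores[:, AA_ALPHABET.index("A")] = [2, -2] * 6
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # 12 residues is the point of the toy
        record = ProteinRecord(id="toy", sequence=seq)
    pssm = PSSMatrix(protein_id="toy", scores=scores)
    profile = StructuralProfile(protein_id="toy", ss=ss, rsa=rsa)

    hi = 1.0 / (1.0 + np.exp(-2.0))  # expit(2)
    lo = 1.0 - hi  # expit(-2)
    expected = {
        "Con_SS_C": 4 / 12,
        "Con_SS_H": 4 / 12,
        "Con_SS_E": 4 / 12,
        "AAC_Res_A": 4 / 12,
        "AAC_Res_C": 1 / 12,
        "AAC_Res_K": 2 / 12,
        "AAC_Res_W": 0.0,
        "AAC_Res_A_SS_H": 2 / 12,
        "AAC_Res_A_Ex_0.3": 2 / 12,
        "AAC_Res_A_Bu_0.3": 2 / 12,
        "DIC_Res_AA": 1 / 11,
        "DIC_Res_AC": 1 / 11,
        "DIC_Res_KE": 1 / 11,
        "DIC_Res_WW": 0.0,
        "AveRSA_Res_A": (0.8 + 0.1 + 0.0 + 0.4) / 4,
        "AveRSA_SS_H": (0.8 + 0.1 + 0.5 + 0.3) / 4,
        "AveRSA_Res_A_SS_H": (0.8 + 0.1) / 2,
        "AveRSA_Res_W": 0.0,
        "AvePscore_AA_A": 0.5,  # expit(2) + expit(-2) = 1
        "AvePscore_AA_C": 0.5,  # constant-zero column
        "AvePscore_AA_A_Res_K": lo,  # rows 6 and 8 (1-based) both carry -2
        "AvePscore_AA_A_Res_W": 0.0,
        "Pscore_AA_A_P_0": lo,
        "Pscore_AA_A_P_25": lo,
        "Pscore_AA_A_P_50": lo,
        "Pscore_AA_A_P_75": hi,
        "Pscore_AA_A_P_100": hi,
        "AutoCC_AA_A_Lag_1": -11 / 12,
        "AutoCC_AA_A_Lag_2": 10 / 12,
        "AutoCC_AA_C_Lag_1": 0.0,  # zero-variance column
        "AutoCC_AA_C_Lag_10": 0.0,
    }
    return {"record": record, "pssm": pssm, "profile": profile, "expected": expected}
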