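"""Seeded generators for morphometric tables and diverged alignments.

The morphometric model has a single latent isometric size factor per
specimen plus group-specific shape offsets and allometric deviations:

    log x_j = s * (1 + beta_dev_j) + mu_shape_j + eps_j,
    s ~ Normal(mean_log_size, size_sd),  eps_j ~ Normal(0, resid_sd_j)

with the shape offsets constrained to sum to zero (they live in shape
space), so adding them never changes expected isosize.

Sequence sets are evolved star-wise from a single root draw under a GTR
rate matrix scaled to one expected substitution per site per unit branch
length, so branch lengths are true evolutionary distances; shared indels
are inserted post hoc as identical gap runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .moldist import AlignedSeqSet
from .tables import DEFAULT_CHARACTERS, MeasurementTable, load_reference_moments

__all__ = [
    "MorphoGroup",
    "MorphoGenSpec",
    "SeqGenSpec",
    "IndelEvent",
    "gen_morpho",
    "gen_alignment",
    "gen_pair",
    "reference_morpho_spec",
]


# ----------------------------------------------------------------------
# morphometric generator

@dataclass(frozen=True)
class MorphoGroup:
    """Parameters for one OTU x sex group."""

    label: str
    sex: str
    n: int
    mean_log_size: float
    size_sd: float
    shape_offset: np.ndarray  # length p, sums to 0
    allometric_dev: np.ndarray | float = 0.0  # beta_dev per character
    resid_sd: np.ndarray | float = 0.02

    def validate(self, p: int) -> None:
        if self.n < 1:
            raise ValueError(f"group {self.label}: n must be >= 1")
        off = np.asarray(self.shape_offset, dtype=float)
        if off.shape != (p,):
            raise ValueError(f"group {self.label}: shape offset length != {p}")
        if abs(off.sum()) > 1e-8:
            raise ValueError(f"group {self.label}: shape offsets must sum to 0")
        if self.size_sd < 0 or np.any(np.asarray(self.resid_sd) < 0):
            raise ValueError(f"group {self.label}: SDs must be >= 0")


@dataclass(frozen=True)
class MorphoGenSpec:
    groups: tuple[MorphoGroup, ...]
    characters: tuple[str, ...] = DEFAULT_CHARACTERS
    seed: int = 0

    def validate(self) -> None:
        p = len(self.characters)
        if p < 2:
            raise ValueError("need at least 2 characters")
        for g in self.groups:
            g.validate(p)


def gen_morpho(spec: MorphoGenSpec) -> MeasurementTable:
    """Generate a measurement table; byte-deterministic per seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    p = len(spec.characters)
    frames = []
    counter = 0
    for g in spec.groups:
        s = rng.normal(g.mean_log_size, g.size_sd, size=g.n)
        beta = np.broadcast_to(
            np.asarray(g.allometric_dev, dtype=float), (p,)
        )
        resid = np.broadcast_to(np.asarray(g.resid_sd, dtype=float), (p,))
        eps = rng.normal(0.0, 1.0, size=(g.n, p)) * resid
        logx = s[:, None] * (1.0 + beta)[None, :] + np.asarray(
            g.shape_offset, dtype=float
        )[None, :] + eps
        ids = [f"{g.label}_{g.sex[0]}{counter + i:04d}" for i in range(g.n)]
        counter += g.n
        df = pd.DataFrame(np.exp(logx), columns=list(spec.characters))
        df.insert(0, "sex", g.sex)
        df.insert(0, "otu", g.label)
        df.insert(0, "specimen_id", ids)
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    return MeasurementTable.from_dataframe(table, characters=spec.characters)


def planted_ratio_spec(
    pair: tuple[int, int] = (15, 9),
    d_true: float = 6.0,
    n_per_group: int = 30,
    resid_sd: float = 0.03,
    size_sd: float = 0.05,
    equal_size: bool = True,
    seed: int = 0,
    characters: tuple[str, ...] = DEFAULT_CHARACTERS,
) -> MorphoGenSpec:
    """Two-group spec with one planted discriminating ratio.

    The group mean difference is placed along (e_j - e_k); with isotropic
    residual sd the standard distance of the planted ratio is
    sqrt(2) * offset / resid_sd, so offset = d_true * resid_sd / sqrt(2).
    Every other pair sharing one character has half that separation.
    """
    p = len(characters)
    j, k = pair
    off = np.zeros(p)
    half = d_true * resid_sd / np.sqrt(2.0) / 2.0
    off[j], off[k] = half, -half
    base = 6.0
    g1 = MorphoGroup("sp1", "female", n_per_group, base, size_sd, off,
                     resid_sd=resid_sd)
    g2 = MorphoGroup("sp2", "female", n_per_group,
                     base if equal_size else base + 0.2,
                     size_sd, -off, resid_sd=resid_sd)
    return MorphoGenSpec((g1, g2), characters=characters, seed=seed)


def reference_morpho_spec(seed: int = 0, n_override: int | None = None,
                          sex: str | None = None) -> MorphoGenSpec:
    """Spec calibrated to the bundled five-species group moments.

    Per group: mean log size = mean of per-character log-scale means; shape
    offset = per-character log mean minus that size; per-character residual
    SD chosen so total log-scale variance matches the reference SDs given a
    shared latent size SD.
    """
    mom = load_reference_moments()
    if sex is not None:
        mom = mom[mom["sex"] == sex]
    groups = []
    for (otu, sx), sub in mom.groupby(["otu", "sex"], sort=True):
        sub = sub.set_index("character").loc[list(DEFAULT_CHARACTERS)]
        m = sub["mean"].to_numpy(float)
        sd = sub["sd"].to_numpy(float)
        n = int(sub["n"].iloc[0])
        # log-normal moment matching per character
        sigma2 = np.log1p((sd / m) ** 2)
        mu_log = np.log(m) - sigma2 / 2.0
        size_mu = mu_log.mean()
        offset = mu_log - size_mu
        # shared size factor absorbs the common variance floor
        size_sd = float(np.sqrt(sigma2.min()) * 0.8)
        resid = np.sqrt(np.clip(sigma2 - size_sd**2, 1e-6, None))
        groups.append(
            MorphoGroup(
                label=str(otu), sex=str(sx),
                n=n_override if n_override is not None else n,
                mean_log_size=float(size_mu), size_sd=size_sd,
                shape_offset=offset, resid_sd=resid,
            )
        )
    return MorphoGenSpec(tuple(groups), seed=seed)


# ----------------------------------------------------------------------
# sequence generator

@dataclass(frozen=True)
class IndelEvent:
    """Shared gap run: columns [start, start+span) gapped in ``taxa``."""

    start: int
    span: int
    taxa: tuple[str, ...]


@dataclass(frozen=True)
class SeqGenSpec:
    """Star-shaped divergence scenario.

    ``otus`` maps OTU label -> number of taxa.  Every OTU ancestor sits at
    ``between_d / 2`` substitutions/site from the root; every taxon at
    ``within_d / 2`` from its OTU ancestor, so expected pairwise distances
    are ``within_d`` within OTUs and ``between_d`` between them.
    """

    otus: dict[str, int]
    between_d: float = 0.05
    within_d: float = 0.0
    length: int = 1000
    freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    exchangeabilities: tuple[float, ...] = (1, 1, 1, 1, 1, 1)  # AC AG AT CG CT GT
    indels: tuple[IndelEvent, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.between_d < 0 or self.within_d < 0:
            raise ValueError("distances must be >= 0")
        f = np.asarray(self.freqs, dtype=float)
        if f.shape != (4,) or abs(f.sum() - 1) > 1e-8 or np.any(f <= 0):
            raise ValueError("freqs must be 4 positive values summing to 1")
        if len(self.exchangeabilities) != 6 or any(
            r <= 0 for r in self.exchangeabilities
        ):
            raise ValueError("need 6 positive exchangeabilities")
        if self.length < 1:
            raise ValueError("length must be >= 1")


def _gtr_rate_matrix(freqs, exch) -> np.ndarray:
    """GTR rate matrix scaled to 1 expected substitution per site per unit
    branch length."""
    pi = np.asarray(freqs, dtype=float)
    r = np.zeros((4, 4))
    idx = [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]
    for (i, j), x in zip(idx, exch):
        r[i, j] = r[j, i] = x
    q = r * pi[None, :]
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -(pi * np.diag(q)).sum()
    return q / mu


def _evolve(parent: np.ndarray, q: np.ndarray, d: float,
            rng: np.random.Generator) -> np.ndarray:
    if d == 0:
        return parent.copy()
    p = expm(q * d)
    child = np.empty_like(parent)
    for base in range(4):
        sel = parent == base
        child[sel] = rng.choice(4, size=int(sel.sum()), p=p[base])
    return child


def gen_alignment(spec: SeqGenSpec) -> AlignedSeqSet:
    """Generate an aligned sequence set; byte-deterministic per seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    pi = np.asarray(spec.freqs, dtype=float)
    q = _gtr_rate_matrix(pi, spec.exchangeabilities)
    root = rng.choice(4, size=spec.length, p=pi)
    ids, otus, seqs = [], [], []
    for otu in sorted(spec.otus):
        ancestor = _evolve(root, q, spec.between_d / 2.0, rng)
        for t in range(spec.otus[otu]):
            taxon = _evolve(ancestor, q, spec.within_d / 2.0, rng)
            ids.append(f"{otu}_{t + 1}")
            otus.append(otu)
            seqs.append("".join("ACGT"[b] for b in taxon))
    # apply shared indels post hoc
    for ev in spec.indels:
        if ev.start < 1 or ev.start + ev.span >= spec.length:
            raise ValueError("indel must be internal to the alignment")
        for i, sid in enumerate(ids):
            if sid in ev.taxa or otus[i] in ev.taxa:
                s = seqs[i]
                seqs[i] = s[: ev.start] + "-" * ev.span + s[ev.start + ev.span:]
    return AlignedSeqSet(tuple(ids), tuple(otus), tuple(seqs))


def gen_pair(
    d: float, length: int = 10_000, seed: int = 0,
    freqs=(0.25, 0.25, 0.25, 0.25), exchangeabilities=(1, 1, 1, 1, 1, 1),
) -> AlignedSeqSet:
    """Two sequences at true evolutionary distance d."""
    spec = SeqGenSpec(
        otus={"a": 1, "b": 1}, between_d=d, within_d=0.0, length=length,
        freqs=freqs, exchangeabilities=exchangeabilities, seed=seed,
    )
    return gen_alignment(spec)
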