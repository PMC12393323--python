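"""Synthetic LBP-trial cohort generation.

Simulates a single-arm trial of a live biotherapeutic product (LBP): a
cohort of participants, each carrying 1-4 private endogenous strains of
the LBP species, sampled repeatedly at a chosen per-site sequencing
depth, with a single shared simulated LBP (sLBP) strain spiked into every
sample at a known fraction. Each strain is a binary haplotype over
biallelic SNV sites; observed data are per-site reference/alternate
allele counts ("metagenotypes") drawn from a binomial read model.

The generator is fully seeded: one master seed per cohort, with child
seeds split deterministically per (participant, sample) via
``numpy.random.SeedSequence`` so any sample can be regenerated in
isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StrainGenotype",
    "CohortDesign",
    "SampleComposition",
    "Metagenotype",
    "Cohort",
    "simulate_strain_genotypes",
    "build_cohort_design",
    "draw_sample_composition",
    "spike_lbp",
    "render_metagenotype",
    "simulate_cohort",
    "write_cohort_truth",
    "write_metagenotypes",
    "read_metagenotypes",
]

LBP_STRAIN_ID = "sLBP"

DEFAULT_DEPTHS = (5, 10, 20, 30)
DEFAULT_LBP_LEVELS = tuple(round(0.1 * i, 1) for i in range(11))


@dataclass(frozen=True)
class StrainGenotype:
    """A named binary allele vector (0 = reference, 1 = alternate)."""

    strain_id: str
    alleles: np.ndarray

    def __post_init__(self) -> None:
        alleles = np.asarray(self.alleles, dtype=np.int8)
        if alleles.ndim != 1 or alleles.size == 0:
            raise ValueError("alleles must be a non-empty 1-D vector")
        if not np.isin(alleles, (0, 1)).all():
            raise ValueError("alleles must be 0/1")
        object.__setattr__(self, "alleles", alleles)

    @property
    def n_sites(self) -> int:
        return self.alleles.size


@dataclass(frozen=True)
class SampleComposition:
    """Per-sample relative abundances over strains; fractions sum to 1."""

    sample_id: str
    abundances: dict[str, float]

    def __post_init__(self) -> None:
        if not self.abundances:
            raise ValueError("composition must contain at least one strain")
        vals = np.fromiter(self.abundances.values(), dtype=float)
        if (vals < -1e-12).any():
            raise ValueError("abundances must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"abundances of {self.sample_id!r} sum to {vals.sum():.12f}, not 1"
            )

    @property
    def strain_ids(self) -> list[str]:
        return list(self.abundances)


@dataclass(frozen=True)
class Metagenotype:
    """Observed per-site reference/alternate allele counts for one sample."""

    sample_id: str
    ref_count: np.ndarray
    alt_count: np.ndarray

    def __post_init__(self) -> None:
        ref = np.asarray(self.ref_count, dtype=np.int64)
        alt = np.asarray(self.alt_count, dtype=np.int64)
        if ref.shape != alt.shape or ref.ndim != 1 or ref.size == 0:
            raise ValueError("ref/alt counts must be equal-length non-empty vectors")
        if (ref < 0).any() or (alt < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "ref_count", ref)
        object.__setattr__(self, "alt_count", alt)

    @property
    def n_sites(self) -> int:
        return self.ref_count.size

    @property
    def depth(self) -> np.ndarray:
        """Per-site total coverage."""
        return self.ref_count + self.alt_count

    @property
    def alt_fraction(self) -> np.ndarray:
        """Observed alternate-allele fraction; NaN at zero-coverage sites."""
        total = self.depth
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, self.alt_count / np.maximum(total, 1), np.nan)


@dataclass(frozen=True)
class CohortDesign:
    """Frozen layout of one simulated cohort.

    ``strains_per_participant`` maps participant index to its 1-4 private
    endogenous strain count; ``depth_per_sample`` / ``lbp_level_per_sample``
    assign each sample a nominal per-site coverage and a spike-in fraction.
    """

    n_participants: int
    samples_per_participant: int
    n_sites: int
    strains_per_participant: tuple[int, ...]
    depth_per_sample: dict[str, int]
    lbp_level_per_sample: dict[str, float]
    seed: int
    depth_mode: str = "fixed"  # "fixed" or "poisson"

    def sample_ids(self) -> list[str]:
        return list(self.depth_per_sample)

    def participant_of(self, sample_id: str) -> int:
        return int(sample_id.split("_")[0][1:])

    def endogenous_strain_ids(self, participant: int) -> list[str]:
        k = self.strains_per_participant[participant]
        return [f"P{participant:03d}_E{j}" for j in range(k)]

    def all_endogenous_strain_ids(self) -> list[str]:
        out: list[str] = []
        for p in range(self.n_participants):
            out.extend(self.endogenous_strain_ids(p))
        return out


@dataclass
class Cohort:
    """A fully realized cohort: design, true genotypes/compositions, counts."""

    design: CohortDesign
    genotypes: dict[str, StrainGenotype]
    compositions: dict[str, SampleComposition]
    metagenotypes: dict[str, Metagenotype]

    @property
    def lbp_genotype(self) -> StrainGenotype:
        return self.genotypes[LBP_STRAIN_ID]

    def sample_table(self) -> pd.DataFrame:
        d = self.design
        rows = [
            {
                "sample_id": s,
                "participant": d.participant_of(s),
                "depth": d.depth_per_sample[s],
                "lbp_level": d.lbp_level_per_sample[s],
            }
            for s in d.sample_ids()
        ]
        return pd.DataFrame(rows)


def _child_rng(seed: int, *spawn_key: int) -> np.random.Generator:
    """Deterministic child RNG: master seed split by a fixed spawn key."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=spawn_key))


def simulate_strain_genotypes(
    n_strains: int, n_sites: int, rng_seed: int
) -> list[StrainGenotype]:
    """Draw ``n_strains`` pairwise-distinct random binary genotypes.

    Each site is an independent Bernoulli(0.5) alternate allele; duplicate
    genotypes are rejected and redrawn so every strain is unique. With
    ``n_sites == 1`` and ``n_strains == 2`` the only distinct pair
    {0}, {1} is returned.
    """
    if n_strains < 1 or n_sites < 1:
        raise ValueError("n_strains and n_sites must be positive")
    if n_strains > 2**min(n_sites, 62):
        raise ValueError(
            f"cannot draw {n_strains} distinct genotypes over {n_sites} site(s)"
        )
    rng = np.random.default_rng(rng_seed)
    seen: set[bytes] = set()
    out: list[StrainGenotype] = []
    while len(out) < n_strains:
        alleles = rng.integers(0, 2, size=n_sites, dtype=np.int8)
        key = alleles.tobytes()
        if key in seen:
            continue
        seen.add(key)
        out.append(StrainGenotype(strain_id=f"S{len(out)}", alleles=alleles))
    return out


def build_cohort_design(
    n_participants: int = 100,
    samples_per_participant: int = 4,
    n_sites: int = 10_000,
    depths: tuple[int, ...] = DEFAULT_DEPTHS,
    lbp_levels: tuple[float, ...] = DEFAULT_LBP_LEVELS,
    max_strains_per_participant: int = 4,
    seed: int = 0,
    depth_mode: str = "fixed",
) -> CohortDesign:
    """Randomize the cohort layout.

    Strain counts are uniform on 1..max_strains_per_participant. Depths are
    balanced within each participant: the depth grid is tiled across that
    participant's samples in shuffled order (with 4 samples and 4 depths,
    each participant gets one sample at every depth). Spike-in levels are
    uniform over the level grid, independently per sample.
    """
    if n_participants < 1 or samples_per_participant < 1 or n_sites < 1:
        raise ValueError("counts must be positive")
    if not depths or not lbp_levels:
        raise ValueError("depth and lbp-level sets must be non-empty")
    if depth_mode not in ("fixed", "poisson"):
        raise ValueError(f"unknown depth_mode {depth_mode!r}")
    rng = _child_rng(seed, 0)
    strains_per = tuple(
        int(x)
        for x in rng.integers(1, max_strains_per_participant + 1, size=n_participants)
    )
    depth_per_sample: dict[str, int] = {}
    lbp_per_sample: dict[str, float] = {}
    depth_grid = np.asarray(depths, dtype=int)
    level_grid = np.asarray(lbp_levels, dtype=float)
    for p in range(n_participants):
        tiled = np.tile(depth_grid, -(-samples_per_participant // depth_grid.size))
        tiled = tiled[:samples_per_participant]
        rng.shuffle(tiled)
        for j in range(samples_per_participant):
            sid = f"P{p:03d}_T{j}"
            depth_per_sample[sid] = int(tiled[j])
            lbp_per_sample[sid] = float(rng.choice(level_grid))
    return CohortDesign(
        n_participants=n_participants,
        samples_per_participant=samples_per_participant,
        n_sites=n_sites,
        strains_per_participant=strains_per,
        depth_per_sample=depth_per_sample,
        lbp_level_per_sample=lbp_per_sample,
        seed=seed,
        depth_mode=depth_mode,
    )


def draw_sample_composition(
    participant_strains: list[str],
    rng_seed: int | np.random.Generator,
    alpha: float = 1.0,
    sample_id: str = "sample",
) -> SampleComposition:
    """Draw endogenous strain abundances from a symmetric Dirichlet(alpha)."""
    if not participant_strains:
        raise ValueError("participant must carry at least one strain")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    fracs = rng.dirichlet(np.full(len(participant_strains), float(alpha)))
    return SampleComposition(
        sample_id=sample_id,
        abundances=dict(zip(participant_strains, fracs.tolist())),
    )


def spike_lbp(
    composition: SampleComposition,
    lbp_level: float,
    lbp_id: str = LBP_STRAIN_ID,
) -> SampleComposition:
    """Proportionally spike the LBP strain in at fraction ``lbp_level``.

    Endogenous fractions are rescaled by (1 - lbp_level) so the result
    still sums to 1; at level 1.0 the sample is pure LBP.
    """
    if not 0.0 <= lbp_level <= 1.0:
        raise ValueError("lbp_level must lie in [0, 1]")
    if lbp_id in composition.abundances:
        raise ValueError(f"{lbp_id!r} already present in composition")
    if lbp_level == 0.0:
        return composition
    scaled = {k: v * (1.0 - lbp_level) for k, v in composition.abundances.items()}
    if lbp_level == 1.0:
        scaled = {}
    scaled[lbp_id] = lbp_level
    return replace(composition, abundances=scaled)


def render_metagenotype(
    composition: SampleComposition,
    genotypes: dict[str, StrainGenotype],
    depth: int,
    rng_seed: int | np.random.Generator,
    depth_mode: str = "fixed",
) -> Metagenotype:
    """Draw observed allele counts under the binomial read model.

    At each site the alternate count is Binomial(d, p) with
    p = sum_k pi_k * g_ks and the reference count is d - alt. Under the
    default fixed-depth convention d equals the sample's nominal coverage
    at every site; in ``poisson`` mode d ~ Poisson(depth) per site.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    strains = composition.strain_ids
    missing = [s for s in strains if s not in genotypes]
    if missing:
        raise ValueError(f"no genotype for strain(s) {missing}")
    lengths = {genotypes[s].n_sites for s in strains}
    if len(lengths) != 1:
        raise ValueError(f"genotype lengths differ: {sorted(lengths)}")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    g = np.stack([genotypes[s].alleles for s in strains]).astype(float)
    pi = np.array([composition.abundances[s] for s in strains])
    p = np.clip(pi @ g, 0.0, 1.0)
    n_sites = g.shape[1]
    if depth_mode == "fixed":
        d = np.full(n_sites, depth, dtype=np.int64)
    elif depth_mode == "poisson":
        d = rng.poisson(depth, size=n_sites)
    else:
        raise ValueError(f"unknown depth_mode {depth_mode!r}")
    alt = rng.binomial(d, p)
    return Metagenotype(
        sample_id=composition.sample_id, ref_count=d - alt, alt_count=alt
    )


def simulate_cohort(
    design: CohortDesign,
    lbp_genotype: StrainGenotype | None = None,
    dirichlet_alpha: float = 1.0,
) -> Cohort:
    """Realize a full cohort from its design.

    Endogenous genotypes are drawn per cohort; the sLBP genotype may be
    passed in so one genotype is shared across the cohorts of a study run
    (it is drawn here only when not supplied). Per-sample randomness uses
    child seeds split from ``design.seed`` by (participant, sample) so any
    subset is reproducible in isolation.
    """
    d = design
    geno_rng = _child_rng(d.seed, 1)
    endo_ids = d.all_endogenous_strain_ids()
    n_draw = len(endo_ids) + (0 if lbp_genotype is not None else 1)
    drawn = simulate_strain_genotypes(
        n_draw, d.n_sites, int(geno_rng.integers(2**31))
    )
    genotypes: dict[str, StrainGenotype] = {}
    if lbp_genotype is None:
        lbp_genotype = StrainGenotype(LBP_STRAIN_ID, drawn[-1].alleles)
        drawn = drawn[:-1]
    elif lbp_genotype.n_sites != d.n_sites:
        raise ValueError("lbp genotype length does not match design n_sites")
    genotypes[LBP_STRAIN_ID] = StrainGenotype(LBP_STRAIN_ID, lbp_genotype.alleles)
    for sid, g in zip(endo_ids, drawn):
        genotypes[sid] = StrainGenotype(sid, g.alleles)

    compositions: dict[str, SampleComposition] = {}
    metagenotypes: dict[str, Metagenotype] = {}
    for p in range(d.n_participants):
        strains = d.endogenous_strain_ids(p)
        for j in range(d.samples_per_participant):
            sid = f"P{p:03d}_T{j}"
            rng = _child_rng(d.seed, 2, p, j)
            comp = draw_sample_composition(
                strains, rng, alpha=dirichlet_alpha, sample_id=sid
            )
            comp = spike_lbp(comp, d.lbp_level_per_sample[sid])
            compositions[sid] = comp
            metagenotypes[sid] = render_metagenotype(
                comp, genotypes, d.depth_per_sample[sid], rng, depth_mode=d.depth_mode
            )
    return Cohort(
        design=d,
        genotypes=genotypes,
        compositions=compositions,
        metagenotypes=metagenotypes,
    )


# ---------------------------------------------------------------------------
# Tabular I/O (all TSV, all plain text)


def genotypes_to_frame(genotypes: dict[str, StrainGenotype]) -> pd.DataFrame:
    return pd.DataFrame(
        {sid: g.alleles for sid, g in genotypes.items()}
    ).T.rename_axis("strain_id")


def compositions_to_frame(compositions: dict[str, SampleComposition]) -> pd.DataFrame:
    rows = [
        {"sample_id": sid, "strain_id": k, "abundance": v}
        for sid, comp in compositions.items()
        for k, v in comp.abundances.items()
    ]
    return pd.DataFrame(rows)


def write_cohort_truth(cohort: Cohort, out_dir: str | Path) -> None:
    """Write true genotypes, compositions and the sample table as TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genotypes_to_frame(cohort.genotypes).to_csv(out / "true_genotypes.tsv", sep="\t")
    compositions_to_frame(cohort.compositions).to_csv(
        out / "true_compositions.tsv", sep="\t", index=False
    )
    cohort.sample_table().to_csv(out / "samples.tsv", sep="\t", index=False)


def write_metagenotypes(
    metagenotypes: dict[str, Metagenotype], path: str | Path
) -> None:
    frames = []
    for sid, m in metagenotypes.items():
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sid,
                    "site_index": np.arange(m.n_sites),
                    "ref_count": m.ref_count,
                    "alt_count": m.alt_count,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_metagenotypes(path: str | Path) -> dict[str, Metagenotype]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, Metagenotype] = {}
    for sid, grp in df.groupby("sample_id", sort=False):
        grp = grp.sort_values("site_index")
        out[str(sid)] = Metagenotype(
            sample_id=str(sid),
            ref_count=grp["ref_count"].to_numpy(),
            alt_count=grp["alt_count"].to_numpy(),
        )
    return out
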