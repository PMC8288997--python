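"""Joint-SFS demographic inference by simulation-based composite likelihood.

The observed joint site-frequency spectrum is polarized with an outgroup
(outgroup-heterozygous or missing sites removed; the allele absent from the
homozygous outgroup is the derived allele).  Expected spectra under a
demographic model come from the package's own structured-coalescent
simulator via the branch-length Monte-Carlo estimator: the probability of a
derived-allele configuration (i, j) is proportional to the mean genealogy
branch length subtending i haploid leaves of population 1 and j of
population 2.

Fitting maximizes a composite likelihood over bounded parameters with
common random numbers across evaluations (the same genealogy seeds are
reused for every parameter value, which makes the Monte-Carlo likelihood
surface smooth enough for derivative-free optimization).  Two objectives
are available:

* ``poisson`` (default): per-cell expected SNP counts
  lambda_ij = mu * L * E[branch length], CL = sum m_ij ln lambda_ij -
  lambda_ij.  The total-count term makes absolute sizes and times
  identifiable under a fixed mutation rate.
* ``multinomial``: the shape-only CL = sum m_ij ln p_ij over normalized
  cell probabilities (identifies ratios only).

AIC = 2k - 2 maxCL with natural logs throughout; model ranking is only
meaningful between fits that used the same observed spectrum and objective.
Confidence intervals come from a parametric bootstrap: spectra are
re-simulated under the point estimates and refit.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import GenotypeMatrix, HET, HOM_REF, MISSING
from .synthetic import PopulationModelSpec, joint_branch_lengths, simulate_coalescent


# ===========================================================================
# Joint SFS
# ===========================================================================

@dataclass
class JointSFS:
    """(2n1+1) x (2n2+1) counts of derived-allele frequencies in two
    populations, with masked cells excluded from all totals."""

    n1: int
    n2: int
    counts: np.ndarray
    mask: np.ndarray = None  # True = masked
    sequence_length_bp: float | None = None  # total surveyed length, for rates

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, float)
        expected = (2 * self.n1 + 1, 2 * self.n2 + 1)
        if self.counts.shape != expected:
            raise ValueError(f"counts shape {self.counts.shape}, expected {expected}")
        if self.mask is None:
            self.mask = np.zeros(expected, bool)
            self.mask[0, 0] = True
        if (self.counts[~self.mask] < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total_sites(self) -> float:
        return float(self.counts[~self.mask].sum())

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# sample_sizes_diploid\t{self.n1}\t{self.n2}"
                     f"\t{self.sequence_length_bp or ''}\n")
            masked = ";".join(f"{i},{j}" for i, j in zip(*np.where(self.mask)))
            fh.write(f"# masked_cells\t{masked}\n")
            np.savetxt(fh, self.counts, fmt="%.6g", delimiter="\t")

    @staticmethod
    def from_tsv(path: str | Path) -> "JointSFS":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            n1, n2 = int(header[1]), int(header[2])
            seq_len = float(header[3]) if len(header) > 3 and header[3] else None
            masked_line = fh.readline().rstrip("\n").split("\t")
            counts = np.loadtxt(fh, delimiter="\t", ndmin=2)
        mask = np.zeros((2 * n1 + 1, 2 * n2 + 1), bool)
        if len(masked_line) > 1 and masked_line[1]:
            for cell in masked_line[1].split(";"):
                i, j = map(int, cell.split(","))
                mask[i, j] = True
        return JointSFS(n1, n2, counts, mask, seq_len)


def _derived_counts(gm: GenotypeMatrix, derived_is_alt: np.ndarray) -> np.ndarray:
    """Per-site derived-allele copy totals over non-missing genotypes."""
    alt_copies = np.where(gm.gt == MISSING, 0, gm.gt).sum(axis=1)
    called = (gm.gt != MISSING).sum(axis=1)
    return np.where(derived_is_alt, alt_copies, 2 * called - alt_copies)


def polarize_joint_sfs(gm_pop1: GenotypeMatrix, gm_pop2: GenotypeMatrix,
                       gm_outgroup: GenotypeMatrix,
                       sequence_length_bp: float | None = None,
                       ) -> tuple[JointSFS, dict[str, int]]:
    """Outgroup-polarized joint SFS over the shared site set.

    Sites where the outgroup is heterozygous or missing are removed; the
    ancestral state is the homozygous outgroup allele and the derived allele
    is the other one.  Sites where the outgroup carries neither observed
    allele are counted as unpolarizable.  Full sample occupancy is required
    (sites with missing genotypes in pop1/pop2 are excluded and counted).
    Cell (0, 0) is masked.  Returns ``(sfs, exclusion_counts)``.
    """
    def keyframe(gm):
        return pd.MultiIndex.from_frame(gm.sites[["scaffold", "pos"]])

    k1, k2, ko = keyframe(gm_pop1), keyframe(gm_pop2), keyframe(gm_outgroup)
    common = k1.intersection(k2).intersection(ko)
    i1 = k1.get_indexer(common)
    i2 = k2.get_indexer(common)
    io = ko.get_indexer(common)
    n1, n2 = gm_pop1.n_samples, gm_pop2.n_samples
    counts = np.zeros((2 * n1 + 1, 2 * n2 + 1))
    excl = {"outgroup_het_or_missing": 0, "unpolarizable": 0, "ingroup_missing": 0}
    og = gm_outgroup.gt[io]
    for row in range(len(common)):
        ogt = og[row]
        called = ogt[ogt != MISSING]
        if len(called) == 0 or (called == HET).any():
            excl["outgroup_het_or_missing"] += 1
            continue
        states = set(called[called != HET])
        if len(states) > 1:
            excl["outgroup_het_or_missing"] += 1
            continue
        anc_is_ref = states == {HOM_REF}
        g1 = gm_pop1.gt[i1[row]]
        g2 = gm_pop2.gt[i2[row]]
        if (g1 == MISSING).any() or (g2 == MISSING).any():
            excl["ingroup_missing"] += 1
            continue
        if anc_is_ref:
            d1, d2 = int(g1.sum()), int(g2.sum())
        else:
            d1, d2 = int(2 * n1 - g1.sum()), int(2 * n2 - g2.sum())
        counts[d1, d2] += 1
    sfs = JointSFS(n1, n2, counts, sequence_length_bp=sequence_length_bp)
    return sfs, excl


def truth_polarized_sfs(gm_pop1: GenotypeMatrix, gm_pop2: GenotypeMatrix,
                        sequence_length_bp: float | None = None) -> JointSFS:
    """Joint SFS using the simulator's recorded ancestral alleles as truth."""
    if "ancestral" not in gm_pop1.sites.columns:
        raise ValueError("genotype matrix has no recorded ancestral alleles")
    n1, n2 = gm_pop1.n_samples, gm_pop2.n_samples
    counts = np.zeros((2 * n1 + 1, 2 * n2 + 1))
    derived_is_alt = (gm_pop1.sites["ancestral"] == gm_pop1.sites["ref"]).to_numpy()
    d1 = _derived_counts(gm_pop1, derived_is_alt)
    d2 = _derived_counts(gm_pop2, derived_is_alt)
    for a, b in zip(d1, d2):
        counts[a, b] += 1
    return JointSFS(n1, n2, counts, sequence_length_bp=sequence_length_bp)


# ===========================================================================
# Expected SFS and composite likelihood
# ===========================================================================

def expected_sfs(model: PopulationModelSpec, sample_sizes: Mapping[str, int],
                 n_sims: int = 1000, seed: int = 0,
                 mask: np.ndarray | None = None) -> np.ndarray:
    """Monte-Carlo cell probabilities of the joint SFS under ``model``.

    Branch-length estimator: the probability of an unmasked cell is its mean
    subtending branch length divided by the total over unmasked cells.
    Identical (model, seed) give identical matrices.
    """
    B = joint_branch_lengths(model, sample_sizes, n_sims, seed)
    if mask is None:
        mask = np.zeros_like(B, bool)
        mask[0, 0] = True
        mask[-1, -1] = True  # fixed-derived corner is not polymorphic
    B = B.copy()
    B[mask] = 0.0
    total = B.sum()
    if total <= 0:
        raise ValueError("no polymorphic outcomes simulated; increase n_sims "
                         "or the model's diversity (theta)")
    return B / total


def composite_log_likelihood(obs: JointSFS, expected: np.ndarray,
                             pseudo: float | None = None) -> float:
    """CL = sum over unmasked cells of m_ij * ln max(p_ij, pseudo).

    Natural log; ``pseudo`` floors zero-probability cells (default
    1 / (10 * number of unmasked cells * total observed sites + 10)).
    """
    if expected.shape != obs.counts.shape:
        raise ValueError(f"shape mismatch: obs {obs.counts.shape}, "
                         f"expected {expected.shape}")
    live = ~obs.mask
    if pseudo is None:
        pseudo = 1.0 / (10.0 * live.sum() * max(obs.total_sites, 1.0) + 10.0)
    p = np.maximum(expected[live], pseudo)
    return float(np.sum(obs.counts[live] * np.log(p)))


# ===========================================================================
# Parametrized models
# ===========================================================================

@dataclass(frozen=True)
class FreeParameter:
    name: str
    lower: float
    upper: float
    scale: Literal["linear", "log"] = "log"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.lower) and math.isfinite(self.upper)):
            raise ValueError("bounds must be finite")
        if self.lower >= self.upper:
            raise ValueError("lower bound must be below upper bound")


@dataclass(frozen=True)
class DemographicModel:
    """A demographic-model template with named free parameters.

    ``builder`` maps a {name: value} dict to a concrete
    :class:`PopulationModelSpec`; ``free_parameters`` carries bounds and
    search scale (log scale for sizes and times, linear for migration).
    """

    name: str
    builder: Callable[[Mapping[str, float]], PopulationModelSpec]
    free_parameters: tuple[FreeParameter, ...]

    @property
    def k(self) -> int:
        return len(self.free_parameters)

    def spec(self, values: Mapping[str, float]) -> PopulationModelSpec:
        return self.builder(values)


def split_model_template(n_anc: float | None = None,
                         ne_bounds: tuple[float, float] = (500.0, 1e5),
                         t_bounds: tuple[float, float] = (100.0, 1e5),
                         m_bounds: tuple[float, float] = (0.0, 1e-3),
                         shared_ne: bool = True,
                         with_migration: bool = True,
                         mutation_rate: float | None = None,
                         labels: tuple[str, str] = ("pop1", "pop2"),
                         ) -> DemographicModel:
    """Two-population split, optionally with symmetric migration.

    Free parameters: ``ne`` (current size, shared by both populations when
    ``shared_ne``), ``t_split`` and (optionally) ``m``.  The ancestral size
    defaults to ``ne`` unless ``n_anc`` is fixed.
    """
    mu = mutation_rate if mutation_rate is not None else 1.47e-8

    def build(v: Mapping[str, float]) -> PopulationModelSpec:
        ne = v["ne"]
        ne2 = ne if shared_ne else v["ne2"]
        anc = n_anc if n_anc is not None else ne
        m = v.get("m", 0.0)
        return PopulationModelSpec.two_population_split(
            ne, ne2, anc, v["t_split"], m12=m, m21=m,
            labels=labels, mutation_rate=mu)

    params = [FreeParameter("ne", *ne_bounds, "log")]
    name = "split"
    if not shared_ne:
        params.append(FreeParameter("ne2", *ne_bounds, "log"))
        name += "_free_sizes"
    params.append(FreeParameter("t_split", *t_bounds, "log"))
    if with_migration:
        params.append(FreeParameter("m", *m_bounds, "linear"))
        name += "_migration"
    return DemographicModel(name, build, tuple(params))


def model_from_dict(raw: Mapping) -> DemographicModel:
    """Build a :class:`DemographicModel` from a small declarative schema.

    The schema mirrors :class:`PopulationModelSpec`; any scalar may be a
    ``"$name"`` placeholder bound by ``free_parameters``::

        name: split_migration
        populations: [pop1, pop2]
        epochs:
          pop1: [[0, $ne], [$t_split, $ne]]
          pop2: [[0, $ne]]
        splits: [[$t_split, pop2, pop1]]
        migration: [[0, [[0, $m], [$m, 0]]]]
        mutation_rate: 1.47e-8
        free_parameters:
          - {name: ne, lower: 500, upper: 50000, scale: log}
          - {name: t_split, lower: 300, upper: 30000, scale: log}
          - {name: m, lower: 0, upper: 0.001, scale: linear}
    """
    params = tuple(
        FreeParameter(p["name"], float(p["lower"]), float(p["upper"]),
                      p.get("scale", "log"))
        for p in raw.get("free_parameters", ())
    )
    names = {p.name for p in params}

    def subst(node, values):
        if isinstance(node, str) and node.startswith("$"):
            key = node[1:]
            if key not in names:
                raise ValueError(f"placeholder ${key} has no free parameter")
            return float(values[key])
        if isinstance(node, Mapping):
            return {k: subst(v, values) for k, v in node.items()}
        if isinstance(node, (list, tuple)):
            return [subst(v, values) for v in node]
        return node

    def build(values: Mapping[str, float]) -> PopulationModelSpec:
        populations = tuple(raw["populations"])
        epochs = {p: tuple((float(t), float(n)) for t, n in ep)
                  for p, ep in subst(raw["epochs"], values).items()}
        splits = tuple((float(t), d, a)
                       for t, d, a in subst(raw.get("splits", ()), values))
        migration = tuple(
            (float(t), tuple(tuple(float(m) for m in row) for row in mat))
            for t, mat in subst(raw.get("migration", ()), values))
        return PopulationModelSpec(
            populations, epochs, splits, migration,
            mutation_rate=float(raw.get("mutation_rate", 1.47e-8)))

    return DemographicModel(str(raw.get("name", "custom")), build, params)


def model_from_yaml(path: str | Path) -> DemographicModel:
    """Load a demographic-model template from a YAML file (see
    :func:`model_from_dict` for the schema)."""
    import yaml
    with open(path) as fh:
        return model_from_dict(yaml.safe_load(fh))


# ===========================================================================
# Fitting
# ===========================================================================

@dataclass
class FitResult:
    model_name: str
    estimates: dict[str, float]
    max_cl: float
    aic: float
    k: int
    converged: bool
    n_starts: int
    objective: str
    trace: list[dict] = field(default_factory=list)
    ci: dict[str, tuple[float, float]] | None = None
    ci_flag: str | None = None
    obs_id: int | None = None  # identity of the observed spectrum

    def to_json_dict(self) -> dict:
        return {
            "model": self.model_name, "estimates": self.estimates,
            "max_cl": self.max_cl, "aic": self.aic, "k": self.k,
            "converged": self.converged, "objective": self.objective,
            "ci": self.ci, "ci_flag": self.ci_flag,
        }


def _encode(model: DemographicModel, values: Mapping[str, float]) -> np.ndarray:
    x = []
    for p in model.free_parameters:
        v = values[p.name]
        x.append(math.log(v) if p.scale == "log" else v)
    return np.array(x)


def _decode(model: DemographicModel, x: np.ndarray) -> dict[str, float]:
    out = {}
    for p, xi in zip(model.free_parameters, x):
        v = math.exp(xi) if p.scale == "log" else xi
        out[p.name] = float(min(max(v, p.lower), p.upper))
    return out


def _objective_factory(obs: JointSFS, model: DemographicModel,
                       sample_sizes: Mapping[str, int], n_sims: int,
                       seed: int, objective: str) -> Callable[[np.ndarray], float]:
    live = ~obs.mask
    m_obs = obs.counts[live]
    total_obs = m_obs.sum()

    def neg_cl(x: np.ndarray) -> float:
        values = _decode(model, x)
        try:
            spec = model.spec(values)
            # common random numbers: same seed at every evaluation
            B = joint_branch_lengths(spec, sample_sizes, n_sims, seed)
        except (ValueError, OverflowError):
            return 1e12
        B = B.copy()
        B[obs.mask] = 0.0
        total_B = B[live].sum()
        if total_B <= 0:
            return 1e12
        if objective == "poisson":
            if obs.sequence_length_bp is None:
                raise ValueError("poisson objective requires sequence_length_bp on the SFS")
            lam = B[live] * spec.mutation_rate * obs.sequence_length_bp
            lam = np.maximum(lam, 1e-300)
            return -float(np.sum(m_obs * np.log(lam)) - lam.sum())
        p = np.maximum(B[live] / total_B, 1e-12)
        return -float(np.sum(m_obs * np.log(p)))

    return neg_cl


def _quadratic_refine(obs: JointSFS, model: DemographicModel,
                      sample_sizes: Mapping[str, int], n_sims: int,
                      objective: str, center: np.ndarray,
                      bounds_x: list[tuple[float, float]],
                      rng: np.random.Generator, shrink: float = 1.0,
                      n_points: int | None = None
                      ) -> tuple[np.ndarray, float, bool]:
    """Response-surface refinement around ``center``.

    The composite likelihood is evaluated at Sobol points in a local box,
    each with an independent genealogy seed, and a full quadratic surface is
    fit by least squares; its constrained maximizer replaces the center.
    Because the Monte-Carlo errors are independent across points, the
    regression averages them away — unlike common-random-number search,
    whose frozen noise displaces the optimum along flat ridges.
    """
    k = model.k
    if n_points is None:
        n_points = 32 * k
    n_points = 1 << max(5, (n_points - 1).bit_length())  # power of 2 for Sobol
    half = []
    for j, p in enumerate(model.free_parameters):
        if p.scale == "log":
            half.append(0.30 * shrink)
        else:
            lo, hi = bounds_x[j]
            half.append(shrink * max(0.25 * abs(center[j]), 0.04 * (hi - lo)))
    lo_box = np.array([max(center[j] - half[j], bounds_x[j][0]) for j in range(k)])
    hi_box = np.array([min(center[j] + half[j], bounds_x[j][1]) for j in range(k)])
    sampler = stats.qmc.Sobol(d=k, seed=int(rng.integers(2 ** 31 - 1)))
    pts = lo_box + sampler.random(n_points) * (hi_box - lo_box)
    fs = np.empty(n_points)
    for i, x in enumerate(pts):
        f = _objective_factory(obs, model, sample_sizes, n_sims,
                               int(rng.integers(2 ** 31 - 1)), objective)
        fs[i] = f(x)
    # quadratic design matrix on standardized coordinates
    scale = (hi_box - lo_box) / 2.0
    mid = (hi_box + lo_box) / 2.0
    Z = (pts - mid) / scale
    cols = [np.ones(n_points)]
    cols += [Z[:, j] for j in range(k)]
    cols += [Z[:, i] * Z[:, j] for i in range(k) for j in range(i, k)]
    A = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(A, fs, rcond=None)
    g = coef[1:k + 1]
    H = np.zeros((k, k))
    idx = k + 1
    for i in range(k):
        for j in range(i, k):
            if i == j:
                H[i, i] = 2 * coef[idx]
            else:
                H[i, j] = H[j, i] = coef[idx]
            idx += 1
    best_sampled = int(np.argmin(fs))
    cand = [(pts[best_sampled], False)]
    evals = np.linalg.eigvalsh(H)
    interior = False
    if evals.min() > 1e-9:  # proper minimum of the fitted neg-CL bowl
        z_star = np.linalg.solve(H, -g)
        interior = bool(np.all(np.abs(z_star) < 0.999))
        z_star = np.clip(z_star, -1.0, 1.0)
        cand.append((mid + z_star * scale, interior))
    # validate candidates with one common high-precision seed
    f_val = _objective_factory(obs, model, sample_sizes, 4 * n_sims,
                               int(rng.integers(2 ** 31 - 1)), objective)
    scored = [(f_val(x), x, inter) for x, inter in cand]
    scored.sort(key=lambda t: t[0])
    return scored[0][1], float(scored[0][0]), scored[0][2]


def fit_model(obs: JointSFS, model: DemographicModel,
              sample_sizes: Mapping[str, int], n_sims_per_eval: int = 200,
              optimizer: Literal["nelder_mead", "ecm_like"] = "nelder_mead",
              n_starts: int = 4, max_cycles: int = 40, min_cycles: int = 20,
              seed: int = 0, objective: Literal["poisson", "multinomial"] = "poisson",
              medium_factor: int = 10, polish_factor: int = 25,
              refine_points: tuple[int, int] = (64, 128)) -> FitResult:
    """Maximize the composite likelihood over the model's free parameters.

    Every likelihood evaluation within a stage reuses the same genealogy
    seeds (common random numbers), which freezes the Monte-Carlo noise and
    makes the surface smooth for derivative-free search — but the frozen
    noise also displaces the surface optimum, by an amount that shrinks as
    the per-evaluation simulation count grows.  The search therefore runs
    in three precision stages:

    1. a Sobol scan of the bounded box at ``n_sims_per_eval`` genealogies
       per evaluation, to locate promising basins cheaply;
    2. ``optimizer`` runs from the ``n_starts`` best scan points at
       ``medium_factor`` x the simulation count (``ecm_like`` cycles
       bounded one-dimensional maximizations, between ``min_cycles`` and
       ``max_cycles`` cycles; ``nelder_mead`` runs a simplex with an
       evaluation budget proportional to ``max_cycles``);
    3. a final simplex polish of the best run at ``polish_factor`` x the
       simulation count under fresh common random numbers.

    Returns the best replicate; flagged non-converged if no optimizer run
    reported success.
    """
    if model.k < 1:
        raise ValueError("model must have at least one free parameter")
    rng = np.random.default_rng(seed)
    crn_seed = int(rng.integers(2 ** 31 - 1))
    neg_cl_scan = _objective_factory(obs, model, sample_sizes, n_sims_per_eval,
                                     crn_seed, objective)
    neg_cl = _objective_factory(obs, model, sample_sizes,
                                n_sims_per_eval * max(medium_factor, 1),
                                crn_seed + 1, objective)
    bounds_x = []
    for p in model.free_parameters:
        lo = math.log(max(p.lower, 1e-12)) if p.scale == "log" else p.lower
        hi = math.log(p.upper) if p.scale == "log" else p.upper
        bounds_x.append((lo, hi))
    best_x, best_f, converged = None, math.inf, False
    trace = []
    # cheap scan over the box: evaluations are inexpensive at coarse
    # precision, and starting the simplex from the best scan points is far
    # more robust than random restarts on ridged surfaces
    n_scan = 1 << max(6, (64 * model.k - 1).bit_length())  # power of 2 for Sobol
    sampler = stats.qmc.Sobol(d=model.k, seed=int(rng.integers(2 ** 31 - 1)))
    unit = sampler.random(n_scan)
    lo = np.array([b[0] for b in bounds_x])
    hi = np.array([b[1] for b in bounds_x])
    scan_pts = lo + unit * (hi - lo)
    scan_f = np.array([neg_cl_scan(p) for p in scan_pts])
    # re-rank the best scan points at medium precision before starting
    shortlist = scan_pts[np.argsort(scan_f)[:max(4 * n_starts, n_starts)]]
    short_f = np.array([neg_cl(p) for p in shortlist])
    starts = shortlist[np.argsort(short_f)[:n_starts]]
    for s in range(n_starts):
        x0 = starts[s]
        if optimizer == "nelder_mead":
            res = optimize.minimize(
                neg_cl, x0, method="Nelder-Mead",
                bounds=bounds_x,
                options={"maxfev": max_cycles * (1 + model.k),
                         "xatol": 2e-3, "fatol": 0.05},
            )
            x, f, ok = res.x, res.fun, bool(res.success)
        else:  # ecm_like: conditional 1-D maximizations, cycled
            x = x0.copy()
            f = neg_cl(x)
            ok = False
            for cycle in range(max_cycles):
                f_before = f
                for d in range(model.k):
                    lo, hi = bounds_x[d]

                    def f1(v, d=d):
                        xt = x.copy()
                        xt[d] = v
                        return neg_cl(xt)

                    r = optimize.minimize_scalar(f1, bounds=(lo, hi),
                                                 method="bounded",
                                                 options={"xatol": 1e-3})
                    if r.fun < f:
                        x[d] = r.x
                        f = r.fun
                if cycle + 1 >= min_cycles and f_before - f < 1e-3:
                    ok = True
                    break
        trace.append({"start": s, "x0": list(x0), "f": float(f), "converged": ok})
        if f < best_f:
            best_x, best_f, converged = x, f, ok
    if polish_factor > 1:
        # walk along soft ridges: repeat full-size boxes while the fitted
        # optimum lands on the box edge, then one shrunken final round
        for round_i in range(4):
            best_x, best_f, interior = _quadratic_refine(
                obs, model, sample_sizes, n_sims_per_eval * polish_factor,
                objective, best_x, bounds_x, rng, shrink=1.0,
                n_points=refine_points[0])
            trace.append({"start": f"walk{round_i}", "x0": list(best_x),
                          "f": float(best_f), "converged": True})
            if interior:
                break
        best_x, best_f, _ = _quadratic_refine(
            obs, model, sample_sizes, n_sims_per_eval * polish_factor,
            objective, best_x, bounds_x, rng, shrink=0.5,
            n_points=refine_points[1])
        trace.append({"start": "refine", "x0": list(best_x),
                      "f": float(best_f), "converged": True})
        converged = True  # the refinement stage always runs to completion
    estimates = _decode(model, best_x)
    max_cl = -best_f
    return FitResult(model.name, estimates, max_cl, 2 * model.k - 2 * max_cl,
                     model.k, converged, n_starts, objective, trace,
                     obs_id=id(obs))


def revalidate_cl(fits: Sequence[FitResult], models: Sequence[DemographicModel],
                  obs: JointSFS, sample_sizes: Mapping[str, int],
                  n_sims: int = 2000, seed: int = 0,
                  n_seeds: int = 8) -> list[FitResult]:
    """Recompute each fit's composite likelihood at its point estimates,
    averaging evaluations over ``n_seeds`` genealogy seeds shared by all
    models.

    Monte-Carlo CLs from independent optimizer runs are not directly
    comparable (each carries its own frozen noise); shared seeds couple the
    models' evaluations and averaging over several seeds shrinks the
    residual evaluation noise below the AIC penalty scale.
    """
    out = []
    for fit, model in zip(fits, models):
        x = _encode(model, fit.estimates)
        cl = 0.0
        for s in range(n_seeds):
            f = _objective_factory(obs, model, sample_sizes, n_sims,
                                   seed + s, fit.objective)
            cl += -f(x)
        cl /= n_seeds
        out.append(dataclasses.replace(fit, max_cl=cl, aic=2 * fit.k - 2 * cl))
    return out


def compare_models_aic(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Rank fits of the same observed SFS by AIC (ascending)."""
    if len({f.obs_id for f in fits if f.obs_id is not None}) > 1:
        raise ValueError("fits compare different observed spectra")
    rows = [{"model": f.model_name, "k": f.k, "max_cl": f.max_cl, "aic": f.aic}
            for f in fits]
    out = pd.DataFrame(rows).sort_values(["aic", "k"], kind="stable").reset_index(drop=True)
    out["delta_aic"] = out["aic"] - out["aic"].iloc[0]
    return out


def bootstrap_ci(best_fit: FitResult, model: DemographicModel,
                 sample_sizes: Mapping[str, int], n_loci: int,
                 locus_length_bp: int, n_boot: int = 100,
                 refits_per_spectrum: int = 2, n_sims_per_eval: int = 200,
                 seed: int = 0, level: float = 0.95,
                 medium_factor: int = 5, polish_factor: int = 5,
                 refine_points: tuple[int, int] = (32, 32)) -> FitResult:
    """Parametric-bootstrap percentile CIs for every free parameter.

    Spectra are simulated under the point estimates (same locus structure as
    the observed data), each refit ``refits_per_spectrum`` times keeping the
    better run; CI bounds are the 2.5/97.5 percentiles of the refitted
    estimates, widened if necessary to contain the point estimate.  Flagged
    unreliable when more than 20% of refits fail to converge, and degenerate
    when ``n_boot`` < 10.
    """
    if not best_fit.converged:
        raise ValueError("bootstrap requires a converged point fit")
    spec = model.spec(best_fit.estimates)
    rng = np.random.default_rng(seed)
    draws: dict[str, list[float]] = {p.name: [] for p in model.free_parameters}
    n_bad = 0
    pops = [p for p in spec.populations if sample_sizes.get(p, 0) > 0]
    for b in range(n_boot):
        gm = simulate_coalescent(spec, sample_sizes, n_loci, locus_length_bp,
                                 seed=int(rng.integers(2 ** 31 - 1)))
        gm1 = gm.subset_samples([s for s in gm.samples if s.startswith(pops[0] + "_")])
        gm2 = gm.subset_samples([s for s in gm.samples if s.startswith(pops[1] + "_")])
        sfs = truth_polarized_sfs(gm1, gm2,
                                  sequence_length_bp=n_loci * locus_length_bp)
        fit = fit_model(sfs, model, sample_sizes, n_sims_per_eval,
                        n_starts=refits_per_spectrum,
                        seed=int(rng.integers(2 ** 31 - 1)),
                        objective=best_fit.objective,
                        medium_factor=medium_factor,
                        polish_factor=polish_factor,
                        refine_points=refine_points)
        if not fit.converged:
            n_bad += 1
        for name, v in fit.estimates.items():
            draws[name].append(v)
    alpha = (1 - level) / 2
    ci = {}
    for name, vals in draws.items():
        lo, hi = np.percentile(vals, [100 * alpha, 100 * (1 - alpha)])
        point = best_fit.estimates[name]
        ci[name] = (float(min(lo, point)), float(max(hi, point)))
    flag = None
    if n_bad > 0.2 * n_boot:
        flag = "unreliable: >20% of bootstrap refits did not converge"
    if n_boot < 10:
        flag = ((flag + "; ") if flag else "") + "degenerate: n_boot < 10"
    return dataclasses.replace(best_fit, ci=ci, ci_flag=flag)
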