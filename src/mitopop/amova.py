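"""Hierarchical analysis of molecular variance (AMOVA) with Phi statistics.

Variation among samples is partitioned from a matrix of squared pairwise
distances (here: pairwise nucleotide difference counts, used directly as the
squared Euclidean distances of the underlying framework).  With two grouping
levels — populations nested in groups — the total variance splits into

    sigma2_a  among groups            (Phi_CT = sigma2_a / sigma2_total)
    sigma2_b  among populations
              within groups           (Phi_SC = sigma2_b / (sigma2_b + sigma2_c))
    sigma2_c  within populations      (Phi_ST = (sigma2_a + sigma2_b) / sigma2_total)

Sums of squares are computed from the distance partitions
(SS = sum of d^2 over pairs in a block / block size), variance components
from the expected mean squares with the unbalanced-design coefficients, and
P-values by the standard per-level permutation schemes: samples among
populations (overall) for sigma2_c, samples among populations within their
group for sigma2_b, and whole populations among groups for sigma2_a.
Negative components (possible in unbalanced designs) are reported as-is.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError


@dataclass(frozen=True)
class AmovaDesign:
    """Sample-to-(group, population) assignment for one AMOVA layout.

    For a single-level design pass the same label for group and population
    (or use :meth:`one_level`).
    """

    assignment: tuple[tuple[str, str], ...]  # per sample: (group, population)
    label: str = "design"

    @classmethod
    def one_level(cls, populations: Sequence[str], label: str = "design") -> "AmovaDesign":
        return cls(tuple(("ALL", p) for p in populations), label)

    @classmethod
    def two_level(cls, groups: Sequence[str], populations: Sequence[str],
                  label: str = "design") -> "AmovaDesign":
        if len(groups) != len(populations):
            raise DesignError("groups and populations must align per sample")
        return cls(tuple(zip(groups, populations)), label)

    @classmethod
    def from_tsv(cls, path, label: str = "design") -> tuple["AmovaDesign", list[str]]:
        """Read a `seq_id group population` TSV; returns (design, seq_ids)."""
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"seq_id", "group", "population"}
        if not required.issubset(df.columns):
            raise DesignError(f"design TSV needs columns {sorted(required)}")
        return cls.two_level(df["group"].tolist(), df["population"].tolist(), label), \
            df["seq_id"].tolist()

    @property
    def n_samples(self) -> int:
        return len(self.assignment)

    @property
    def levels(self) -> int:
        return 2 if len({g for g, _ in self.assignment}) > 1 else 1

    def validate(self) -> None:
        pops = {p for _, p in self.assignment}
        if len(pops) < 2:
            raise DesignError("need at least 2 populations")
        pop_group = {}
        for g, p in self.assignment:
            if p in pop_group and pop_group[p] != g:
                raise DesignError(f"population {p!r} assigned to multiple groups")
            pop_group[p] = g


@dataclass(frozen=True)
class AmovaResults:
    """Variance components, Phi statistics, and permutation P-values."""

    components: dict            # {"among_groups", "among_pops_within", "within_pops"}
    percentages: dict
    phi: dict                   # {"phi_st", "phi_sc", "phi_ct"} as applicable
    p: dict                     # P-value per component
    ss: dict                    # sums of squares incl. "total"
    df: dict
    n_perm: int
    seed: int | None
    label: str

    def summary(self) -> pd.DataFrame:
        rows = []
        for key, source in (
            ("among_groups", "Among groups"),
            ("among_pops_within", "Among populations within groups"),
            ("within_pops", "Within populations"),
        ):
            if key not in self.components:
                continue
            rows.append({
                "source": source,
                "df": self.df.get(key, np.nan),
                "SS": self.ss.get(key, np.nan),
                "variance": self.components[key],
                "percentage": self.percentages[key],
                "P": self.p.get(key, np.nan),
            })
        frame = pd.DataFrame(rows)
        phi_rows = pd.DataFrame(
            [{"source": k, "variance": v} for k, v in self.phi.items()]
        )
        return pd.concat([frame, phi_rows], ignore_index=True)


def _ss_within_blocks(d2: np.ndarray, blocks: Sequence[np.ndarray]) -> float:
    """SS = sum over blocks of (sum of squared distances in block) / block size."""
    total = 0.0
    for idx in blocks:
        if len(idx) == 0:
            continue
        sub = d2[np.ix_(idx, idx)]
        total += sub.sum() / (2.0 * len(idx))  # each pair counted twice
    return total


def _decompose(d2: np.ndarray, groups: np.ndarray, pops: np.ndarray) -> dict:
    """Sums of squares, degrees of freedom and variance components."""
    n = d2.shape[0]
    all_idx = [np.arange(n)]
    group_labels = np.unique(groups)
    pop_labels = np.unique(pops)
    group_blocks = [np.flatnonzero(groups == g) for g in group_labels]
    pop_blocks = [np.flatnonzero(pops == p) for p in pop_labels]
    if any(len(b) == 0 for b in pop_blocks):
        raise DesignError("empty population in design")

    ss_total = _ss_within_blocks(d2, all_idx)
    ss_within_groups = _ss_within_blocks(d2, group_blocks)
    ss_within_pops = _ss_within_blocks(d2, pop_blocks)
    ss_ag = ss_total - ss_within_groups            # among groups
    ss_ap = ss_within_groups - ss_within_pops      # among pops within groups
    ss_wp = ss_within_pops                         # within pops

    G = len(group_labels)
    P = len(pop_labels)
    df_ag = G - 1
    df_ap = P - G
    df_wp = n - P

    pop_sizes = {p: np.sum(pops == p) for p in pop_labels}
    group_sizes = {g: np.sum(groups == g) for g in group_labels}
    group_of_pop = {}
    for g, p in zip(groups, pops):
        group_of_pop[p] = g

    # unbalanced-design coefficients for the expected mean squares
    sum_n2_over_g = sum(
        sum(pop_sizes[p] ** 2 for p in pop_labels if group_of_pop[p] == g) / group_sizes[g]
        for g in group_labels
    )
    sum_n2_total = sum(pop_sizes[p] ** 2 for p in pop_labels)
    sum_g2_total = sum(group_sizes[g] ** 2 for g in group_labels)
    n_prime = (n - sum_n2_over_g) / df_ap if df_ap > 0 else 0.0       # n'
    n_dprime = (sum_n2_over_g - sum_n2_total / n) / df_ag if df_ag > 0 else 0.0  # n''
    n_tprime = (n - sum_g2_total / n) / df_ag if df_ag > 0 else 0.0   # n'''

    ms_wp = ss_wp / df_wp if df_wp > 0 else 0.0
    sigma_c = ms_wp
    if df_ap > 0 and n_prime > 0:
        ms_ap = ss_ap / df_ap
        sigma_b = (ms_ap - sigma_c) / n_prime
    else:
        sigma_b = 0.0
    if df_ag > 0 and n_tprime > 0:
        ms_ag = ss_ag / df_ag
        sigma_a = (ms_ag - sigma_c - n_dprime * sigma_b) / n_tprime
    else:
        sigma_a = 0.0
    return {
        "ss": {"among_groups": ss_ag, "among_pops_within": ss_ap,
               "within_pops": ss_wp, "total": ss_total},
        "df": {"among_groups": df_ag, "among_pops_within": df_ap, "within_pops": df_wp},
        "sigma": (sigma_a, sigma_b, sigma_c),
        "n_groups": G, "n_pops": P,
    }


class Amova:
    """AMOVA model over a sample-level squared-distance matrix and a design."""

    def __init__(self, d2: np.ndarray, design: AmovaDesign):
        design.validate()
        d2 = np.asarray(d2, dtype=float)
        if d2.shape != (design.n_samples, design.n_samples):
            raise DesignError("distance matrix does not match design size")
        self.d2 = d2
        self.design = design
        self.groups = np.array([g for g, _ in design.assignment])
        self.pops = np.array([p for _, p in design.assignment])

    def fit(self, n_perm: int = 10000, seed: int | None = None) -> AmovaResults:
        dec = _decompose(self.d2, self.groups, self.pops)
        sigma_a, sigma_b, sigma_c = dec["sigma"]
        two_level = dec["n_groups"] > 1
        if not two_level:
            sigma_a = 0.0
        total = sigma_a + sigma_b + sigma_c
        if any(s < 0 for s in (sigma_a, sigma_b, sigma_c)):
            warnings.warn("negative variance component(s) reported as-is",
                          stacklevel=2)

        def pct(x):
            return 100.0 * x / total if total != 0 else 0.0

        phi = {}
        if total != 0:
            phi["phi_st"] = (sigma_a + sigma_b) / total
        if two_level:
            if sigma_b + sigma_c != 0:
                phi["phi_sc"] = sigma_b / (sigma_b + sigma_c)
            if total != 0:
                phi["phi_ct"] = sigma_a / total

        p = self._permutation_p(dec, n_perm, seed, two_level) if n_perm > 0 else {}

        components = {"within_pops": sigma_c, "among_pops_within": sigma_b}
        percentages = {"within_pops": pct(sigma_c), "among_pops_within": pct(sigma_b)}
        if two_level:
            components["among_groups"] = sigma_a
            percentages["among_groups"] = pct(sigma_a)
        return AmovaResults(
            components=components, percentages=percentages, phi=phi, p=p,
            ss=dec["ss"], df=dec["df"], n_perm=n_perm, seed=seed,
            label=self.design.label,
        )

    def _permutation_p(self, dec: dict, n_perm: int, seed: int | None,
                       two_level: bool) -> dict:
        rng = np.random.default_rng(seed)
        sigma_a_obs, sigma_b_obs, sigma_c_obs = dec["sigma"]
        n = self.d2.shape[0]
        total_obs = sum(dec["sigma"])
        # Phi_ST analogue: permute samples among populations (all labels fixed
        # to positions, sample order shuffled)
        hits_c = hits_b = hits_a = 0
        phi_st_obs = ((sigma_a_obs if two_level else 0.0) + sigma_b_obs) / total_obs \
            if total_obs else 0.0

        group_labels = np.unique(self.groups)
        pop_of_pop_label = {}
        for g, p_ in zip(self.groups, self.pops):
            pop_of_pop_label[p_] = g
        pop_labels = np.unique(self.pops)

        for _ in range(n_perm):
            # (1) samples among populations anywhere -> tests within-pop comp.
            perm = rng.permutation(n)
            dperm = _decompose(self.d2[np.ix_(perm, perm)], self.groups, self.pops)
            sa, sb, sc = dperm["sigma"]
            tot = sa + sb + sc
            phi_st_perm = ((sa if two_level else 0.0) + sb) / tot if tot else 0.0
            if phi_st_perm >= phi_st_obs - 1e-12:
                hits_c += 1
            if two_level:
                # (2) samples among populations within their group
                perm2 = np.arange(n)
                for g in group_labels:
                    idx = np.flatnonzero(self.groups == g)
                    perm2[idx] = idx[rng.permutation(len(idx))]
                d2b = self.d2[np.ix_(perm2, perm2)]
                db = _decompose(d2b, self.groups, self.pops)
                sbb = db["sigma"][1]
                scb = db["sigma"][2]
                phi_sc_perm = sbb / (sbb + scb) if (sbb + scb) else 0.0
                phi_sc_obs = sigma_b_obs / (sigma_b_obs + sigma_c_obs) \
                    if (sigma_b_obs + sigma_c_obs) else 0.0
                if phi_sc_perm >= phi_sc_obs - 1e-12:
                    hits_b += 1
                # (3) whole populations among groups
                perm_groups = {p_: g for p_, g in zip(
                    pop_labels,
                    rng.permutation([pop_of_pop_label[p_] for p_ in pop_labels]),
                )}
                groups_perm = np.array([perm_groups[p_] for p_ in self.pops])
                da = _decompose(self.d2, groups_perm, self.pops)
                saa = da["sigma"][0]
                tot_a = sum(da["sigma"])
                phi_ct_perm = saa / tot_a if tot_a else 0.0
                phi_ct_obs = sigma_a_obs / total_obs if total_obs else 0.0
                if phi_ct_perm >= phi_ct_obs - 1e-12:
                    hits_a += 1

        p = {"within_pops": (hits_c + 1) / (n_perm + 1)}
        if two_level:
            p["among_pops_within"] = (hits_b + 1) / (n_perm + 1)
            p["among_groups"] = (hits_a + 1) / (n_perm + 1)
        else:
            p["among_pops_within"] = p["within_pops"]
        return p


def amova(d2: np.ndarray, design: AmovaDesign, n_perm: int = 10000,
          seed: int | None = None) -> AmovaResults:
    """Functional wrapper around :class:`Amova`."""
    return Amova(d2, design).fit(n_perm=n_perm, seed=seed)
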