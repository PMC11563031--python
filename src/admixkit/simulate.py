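"""Synthetic allele-frequency panels evolving by drift along an admixture graph.

Per SNP, a root frequency p0 is drawn; each drift edge of length l (in
f-statistic units) adds an independent Gaussian increment with variance
l * p0(1-p0) / E[p0(1-p0)], the heterozygosity-scaled law under which every
expected f-statistic is *exactly* the weighted path-overlap linear form of
:mod:`admixkit.graph` (before boundary clipping, which the shipped fixtures
keep below 1% of SNP x branch events).  Admixture nodes mix their parents'
frequencies linearly; leaves are observed through binomial allele sampling.

The named fixtures regenerate, at desk scale, the canonical study designs for
admixture-graph inference: a human-like quartet with a Native-American-analog
population admixed between eastern and western Eurasian lineages, a
recently-admixed population giving a negative f3, five-population variants
that make the mixture proportion identifiable (or not), and a two-event graph
tuned so one f4 is masked to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .graph import AdmixtureGraph, expected_f4
from .panel import FrequencyPanel

__all__ = [
    "SimulationSpec",
    "simulate_panel",
    "paper_fixture",
    "masking_scenario",
    "FIXTURE_NAMES",
]


class SimulationError(ValueError):
    pass


@dataclass
class SimulationSpec:
    """Fully parameterized simulation scenario.

    samples_per_pop is the number of diploid individuals sampled per leaf;
    None means frequencies are observed without sampling noise.
    """

    graph: AdmixtureGraph
    n_snps: int = 200_000
    root_freq_dist: tuple = ("uniform", 0.40, 0.60)
    samples_per_pop: int | None = 25
    n_blocks: int = 100
    seed: int = 0
    name: str = ""
    fit_topologies: dict[str, AdmixtureGraph] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_snps < 1:
            raise SimulationError("n_snps must be >= 1")
        if self.n_blocks < 2:
            raise SimulationError("n_blocks must be >= 2")
        kind = self.root_freq_dist[0]
        if kind == "uniform":
            lo, hi = self.root_freq_dist[1:]
            if not (0.0 < lo < hi < 1.0):
                raise SimulationError("uniform root support must lie within (0, 1)")
        elif kind == "beta":
            a, b = self.root_freq_dist[1:]
            if a <= 0 or b <= 0:
                raise SimulationError("beta parameters must be positive")
        else:
            raise SimulationError(f"unknown root frequency law {kind!r}")
        if self.samples_per_pop is not None and self.samples_per_pop < 1:
            raise SimulationError("samples_per_pop must be >= 1 or None")
        if any(l is None for l in self.graph.lengths.values()):
            raise SimulationError("all branch lengths must be fixed for simulation")
        if any(a is None for a in self.graph.alphas.values()):
            raise SimulationError("all mixture proportions must be fixed for simulation")


def _root_law(dist: tuple):
    """Sampler and E[p(1-p)] for the root frequency law."""
    kind = dist[0]
    if kind == "uniform":
        lo, hi = dist[1], dist[2]
        m = (lo + hi) / 2.0
        het = m * (1 - m) - (hi - lo) ** 2 / 12.0
        return (lambda rng, n: rng.uniform(lo, hi, n)), het
    a, b = dist[1], dist[2]
    ep = a / (a + b)
    ep2 = a * (a + 1) / ((a + b) * (a + b + 1))
    return (lambda rng, n: rng.beta(a, b, n)), ep - ep2


def _max_path_length(graph: AdmixtureGraph) -> float:
    depth = {graph.root: 0.0}
    best = 0.0
    for node in graph.nodes:
        if node == graph.root:
            continue
        vals = []
        for e in graph.edges:
            if e.child == node:
                vals.append(depth[e.parent] + (e.length or 0.0))
        for a in graph.admixtures:
            if a.child == node:
                vals.extend(depth[p] for p in a.parents)
        depth[node] = max(vals)
        best = max(best, depth[node])
    return best


def simulate_panel(
    spec: SimulationSpec, *, return_genotypes: bool = False
) -> FrequencyPanel | tuple[FrequencyPanel, np.ndarray]:
    """Simulate a frequency panel under the spec's admixture graph.

    With ``return_genotypes=True`` also returns an (n_snps, n_individuals)
    diploid genotype matrix (0/1/2) whose per-population means reproduce the
    panel frequencies exactly.
    """
    import warnings

    spec.validate()
    if _max_path_length(spec.graph) > 0.2:
        warnings.warn(
            "a root-to-leaf path exceeds 0.2 drift units; boundary clipping may be common",
            stacklevel=2,
        )
    rng = np.random.default_rng(spec.seed)
    sampler, het = _root_law(spec.root_freq_dist)
    S = spec.n_snps
    p0 = sampler(rng, S)
    scale = p0 * (1.0 - p0) / het
    freqs = {spec.graph.root: p0}
    clipped = 0
    n_drift = 0
    alphas = spec.graph.alphas
    for node in spec.graph.nodes:
        if node == spec.graph.root:
            continue
        parents = spec.graph.parents(node)
        if len(parents) == 1:
            edge = next(e for e in spec.graph.edges if e.child == node)
            raw = freqs[edge.parent] + rng.normal(0.0, 1.0, S) * np.sqrt(edge.length * scale)
            clipped += int(np.count_nonzero((raw < 0.0) | (raw > 1.0)))
            n_drift += S
            freqs[node] = np.clip(raw, 0.0, 1.0)
        else:
            event = next(a for a in spec.graph.admixtures if a.child == node)
            al = alphas[node]
            freqs[node] = al * freqs[event.parents[0]] + (1.0 - al) * freqs[event.parents[1]]

    leaves = spec.graph.leaves
    P = len(leaves)
    obs = np.empty((S, P))
    counts = np.empty((S, P), dtype=np.int64)
    genos = None
    if spec.samples_per_pop is None:
        for j, leaf in enumerate(leaves):
            obs[:, j] = freqs[leaf]
        counts[:] = np.int64(2) ** 30
    else:
        s = spec.samples_per_pop
        if return_genotypes:
            genos = np.empty((S, P * s), dtype=np.int8)
            for j, leaf in enumerate(leaves):
                g = rng.binomial(2, freqs[leaf][:, None], size=(S, s))
                genos[:, j * s : (j + 1) * s] = g
                obs[:, j] = g.sum(axis=1) / (2.0 * s)
        else:
            for j, leaf in enumerate(leaves):
                obs[:, j] = rng.binomial(2 * s, freqs[leaf]) / (2.0 * s)
        counts[:] = 2 * s

    blocks = (np.arange(S) * spec.n_blocks) // S
    panel = FrequencyPanel(
        snp_ids=np.array([f"snp{i:07d}" for i in range(S)]),
        chrom=np.repeat("1", S),
        pos=np.arange(1, S + 1) * 1000,
        freqs=obs,
        counts=counts,
        blocks=blocks,
        pop_names=leaves,
        meta={
            "fixture": spec.name,
            "seed": spec.seed,
            "clip_rate": clipped / max(n_drift, 1),
            "root_freq_dist": spec.root_freq_dist,
        },
    )
    if return_genotypes:
        return panel, genos
    return panel


# ---------------------------------------------------------------------------
# canned fixtures
# ---------------------------------------------------------------------------

FIXTURE_NAMES = (
    "quartet_mixe",
    "quartet_kyrgyz",
    "five_ulchi",
    "five_hungarian",
    "five_swapped",
)

# Human-like lineage analogs: an African outgroup (Baka-analog), western
# Eurasian (French-analog), eastern Eurasian (Han-analog, plus an Ulchi-analog
# splitting closer to the eastern source), and a Native-American analog (Mixe)
# with ~70% eastern / 30% western Eurasian ancestry.  Drift amounts are scaled
# down from the human values so that total root-to-leaf drift stays ~0.02,
# keeping the Gaussian-drift approximation clean (boundary clipping << 1%)
# while preserving the qualitative Z-score patterns at 2e5 SNPs.
_ALPHA_EAST = 0.7


def _graph_quartet_mixe() -> AdmixtureGraph:
    return AdmixtureGraph.from_edges(
        "R",
        [
            ("R", "Baka", 0.010),
            ("R", "EUR", 0.004),
            ("EUR", "WST", 0.002),
            ("WST", "French", 0.006),
            ("WST", "WestSrc", 0.002),
            ("EUR", "EAS", 0.002),
            ("EAS", "Han", 0.006),
            ("EAS", "EastSrc", 0.002),
            ("pAM", "Mixe", 0.005),
        ],
        [("pAM", "EastSrc", "WestSrc", _ALPHA_EAST)],
    )


def _graph_quartet_kyrgyz() -> AdmixtureGraph:
    # recent ~50/50 admixture with a very short terminal branch: the
    # three-population test f3(Kyrgyz; Han, French) is negative in expectation
    return AdmixtureGraph.from_edges(
        "R",
        [
            ("R", "Baka", 0.010),
            ("R", "EUR", 0.004),
            ("EUR", "WST", 0.006),
            ("WST", "French", 0.002),
            ("WST", "WestSrc", 0.001),
            ("EUR", "EAS", 0.006),
            ("EAS", "Han", 0.002),
            ("EAS", "EastSrc", 0.001),
            ("pKY", "Kyrgyz", 0.0005),
        ],
        [("pKY", "EastSrc", "WestSrc", 0.5)],
    )


def _graph_five_ulchi() -> AdmixtureGraph:
    return AdmixtureGraph.from_edges(
        "R",
        [
            ("R", "Baka", 0.010),
            ("R", "EUR", 0.004),
            ("EUR", "WST", 0.004),
            ("WST", "French", 0.006),
            ("WST", "WestSrc", 0.002),
            ("EUR", "EAS", 0.002),
            ("EAS", "Han", 0.006),
            ("EAS", "EA2", 0.006),
            ("EA2", "Ulchi", 0.004),
            ("EA2", "EastSrc", 0.001),
            ("pAM", "Mixe", 0.005),
        ],
        [("pAM", "EastSrc", "WestSrc", _ALPHA_EAST)],
    )


def _graph_five_swapped() -> AdmixtureGraph:
    # same populations, but the Han/Ulchi split order reversed: Han (not
    # Ulchi) is placed closer to Mixe's eastern source
    return AdmixtureGraph.from_edges(
        "R",
        [
            ("R", "Baka", 0.010),
            ("R", "EUR", 0.004),
            ("EUR", "WST", 0.004),
            ("WST", "French", 0.006),
            ("WST", "WestSrc", 0.002),
            ("EUR", "EAS", 0.002),
            ("EAS", "Ulchi", 0.006),
            ("EAS", "EA2", 0.006),
            ("EA2", "Han", 0.004),
            ("EA2", "EastSrc", 0.001),
            ("pAM", "Mixe", 0.005),
        ],
        [("pAM", "EastSrc", "WestSrc", _ALPHA_EAST)],
    )


def _graph_five_hungarian() -> AdmixtureGraph:
    # Hungarian-analog as a sister of the French-analog: adds a population but
    # (nearly) no new constraint on the mixture proportion
    return AdmixtureGraph.from_edges(
        "R",
        [
            ("R", "Baka", 0.010),
            ("R", "EUR", 0.004),
            ("EUR", "WST", 0.002),
            ("WST", "WF", 0.002),
            ("WF", "French", 0.004),
            ("WF", "Hungarian", 0.004),
            ("WST", "WestSrc", 0.002),
            ("EUR", "EAS", 0.002),
            ("EAS", "Han", 0.006),
            ("EAS", "EastSrc", 0.002),
            ("pAM", "Mixe", 0.005),
        ],
        [("pAM", "EastSrc", "WestSrc", _ALPHA_EAST)],
    )


def quartet_alternative_topologies(fourth: str = "Mixe") -> dict[str, AdmixtureGraph]:
    """The four single-admixture placements for a Baka/French/Han/X quartet.

    With four populations there are 6 constraints but 7 free parameters, so
    each placement (the historically correct one and the three incorrect
    ones) can generally fit the same data perfectly; returned with free
    lengths and proportions for fitting.
    """

    def one(admixed: str, others: tuple[str, str, str]) -> AdmixtureGraph:
        o1, o2, o3 = others  # tree (o1,(o2,o3)); admixed draws from o2/o3 lineages
        return AdmixtureGraph.from_edges(
            "R",
            [
                ("R", o1),
                ("R", "I"),
                ("I", "J2"),
                ("J2", o2),
                ("J2", "Src2"),
                ("I", "J3"),
                ("J3", o3),
                ("J3", "Src3"),
                ("pX", admixed),
            ],
            [("pX", "Src2", "Src3", None)],
        )

    # the incorrect placements mirror the reciprocal interpretation: e.g. Han
    # modeled with most ancestry related to the admixed population and a
    # little related to the outgroup
    return {
        fourth: one(fourth, ("Baka", "Han", "French")),
        "Baka": one("Baka", (fourth, "Han", "French")),
        "Han": one("Han", ("French", fourth, "Baka")),
        "French": one("French", ("Han", fourth, "Baka")),
    }


def five_baka_admixed_topology() -> AdmixtureGraph:
    """Misspecified five-population topology: the outgroup modeled as admixed.

    Mixe is placed unadmixed inside the eastern clade and Baka receives
    ancestry from a deep lineage and a western source; with five populations
    this cannot absorb the true Mixe admixture and leaves large residuals.
    """
    return AdmixtureGraph.from_edges(
        "R",
        [
            ("R", "OUT"),
            ("OUT", "DeepSrc"),
            ("R", "EUR"),
            ("EUR", "WST"),
            ("WST", "French"),
            ("WST", "WestSrc"),
            ("EUR", "EAS"),
            ("EAS", "Han"),
            ("EAS", "EA2"),
            ("EA2", "Ulchi"),
            ("EA2", "Mixe"),
            ("pBK", "Baka"),
        ],
        [("pBK", "DeepSrc", "WestSrc", None)],
    )


def random_admixture_graph(seed: int, max_nodes: int = 8) -> AdmixtureGraph:
    """Random small valid graph (for oracle cross-checks and property tests).

    Builds a random rooted binary tree on 2-4 leaves and, node budget
    permitting, converts one leaf into an admixture node with two randomly
    chosen non-descendant sources.
    """
    rng = np.random.default_rng(seed)

    def rl() -> float:
        return float(rng.uniform(0.001, 0.05))

    n_leaves = int(rng.integers(2, 5))
    edges = [("R", "L0", rl()), ("R", "L1", rl())]
    leaves = ["L0", "L1"]
    nodes = 3
    for k in range(2, n_leaves):
        target = leaves[int(rng.integers(len(leaves)))]
        inner, leaf = f"I{k}", f"L{k}"
        edges = [
            (p, inner if c == target else c, l) for p, c, l in edges
        ]
        edges += [(inner, target, rl()), (inner, leaf, rl())]
        leaves.append(leaf)
        nodes += 2
    admixtures = []
    if nodes + 1 <= max_nodes and rng.random() < 0.7:
        victim = leaves[int(rng.integers(len(leaves)))]
        # prefer internal nodes as sources so the leaf set stays intact
        internal = sorted({p for p, c, l in edges})
        candidates = internal if len(internal) >= 2 else sorted(
            ({p for p, c, l in edges} | {c for p, c, l in edges}) - {victim}
        )
        if len(candidates) >= 2:
            s1, s2 = rng.choice(candidates, size=2, replace=False)
            mix = f"p{victim}"
            edges = [(p, c, l) for p, c, l in edges if c != victim] + [
                (mix, victim, rl())
            ]
            admixtures.append((mix, str(s1), str(s2), float(rng.uniform(0.1, 0.9))))
    return AdmixtureGraph.from_edges("R", edges, admixtures)


def paper_fixture(name: str, *, n_snps: int = 200_000, n_blocks: int = 100, seed: int = 0) -> SimulationSpec:
    """A fully parameterized canned scenario by name.

    Names: quartet_mixe, quartet_kyrgyz, five_ulchi, five_hungarian,
    five_swapped.  ``five_swapped`` shares the five_ulchi history but its
    graph carries the wrong Han/Ulchi split order, for use as a misspecified
    fitting topology.
    """
    builders = {
        "quartet_mixe": _graph_quartet_mixe,
        "quartet_kyrgyz": _graph_quartet_kyrgyz,
        "five_ulchi": _graph_five_ulchi,
        "five_hungarian": _graph_five_hungarian,
        "five_swapped": _graph_five_swapped,
    }
    if name not in builders:
        raise SimulationError(
            f"unknown fixture {name!r}; valid names: {', '.join(FIXTURE_NAMES)}"
        )
    return SimulationSpec(graph=builders[name](), n_snps=n_snps, n_blocks=n_blocks,
                          seed=seed, name=name)


# ---------------------------------------------------------------------------
# masking scenario: two admixture events cancelling in one f4
# ---------------------------------------------------------------------------


def masking_scenario(seed: int = 0) -> SimulationSpec:
    """Two-admixture graph in which one f4 permutation is masked to zero.

    Base tree ((A,B),(C,D)); C receives gamma ancestry from an A-side source
    SA (pushing f4(A,B;C,D) positive) and B receives delta from the C-side
    source SC (pushing it negative).  delta is solved in closed form (the
    expectation is linear in delta) so that E f4(A,B;C,D) = 0 despite both
    events; other permutations still reveal the admixture.
    """
    rng = np.random.default_rng(seed)
    gamma = float(rng.uniform(0.10, 0.17))

    def build(delta: float) -> AdmixtureGraph:
        return AdmixtureGraph.from_edges(
            "R",
            [
                ("R", "AB", 0.003),
                ("R", "CD", 0.003),
                ("AB", "SA", 0.002),
                ("SA", "A", 0.006),
                ("AB", "Bb", 0.002),
                ("pB", "B", 0.005),
                ("CD", "SC", 0.002),
                ("pC", "C", 0.005),
                ("CD", "SD", 0.002),
                ("SD", "D", 0.006),
            ],
            [
                ("pC", "SA", "SC", gamma),   # C: gamma from the A-side source
                ("pB", "SC", "Bb", delta),   # B: delta from the C-side source
            ],
        )

    e0 = expected_f4(build(0.0), "A", "B", "C", "D").value
    e1 = expected_f4(build(1.0), "A", "B", "C", "D").value
    if e0 == e1:
        raise SimulationError("degenerate masking construction")
    delta = e0 / (e0 - e1)
    if not (0.0 < delta < 1.0):
        raise SimulationError("no masking proportion in (0, 1) for this draw")
    spec = SimulationSpec(graph=build(float(delta)), seed=seed, name="masking")
    spec.fit_topologies["unmasked"] = build(0.0)
    return spec


def with_seed(spec: SimulationSpec, seed: int) -> SimulationSpec:
    """Copy of a spec with a different random seed."""
    return replace(spec, seed=seed)
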