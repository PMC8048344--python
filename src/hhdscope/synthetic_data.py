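"""Synthetic protein-family generator with planted truth.

Generates paralogous ~78-residue domain families related by a generating
tree, with a planted conservation architecture (hydrophobic-core columns,
cross-helix stabilizing pairs, family-specific conserved columns), a
truncated four-helix outgroup family, controlled within/between-family
identity levels, and embedding of the domains into longer proteins with
random background flanks plus pure-background decoys. Every downstream
stage of the pipeline can therefore be scored against exact truth.

The substitution process is per-site categorical resampling along the
tree (no indels within domains), so alignment columns coincide with
residue positions and planted-column truth stays exact. Identity targets
are met by rescaling branch-length classes (within-clade, subfamily stem,
backbone) with a monotone coupling of the random draws, so the empirical
mean pairwise identities converge by bisection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS, BACKGROUND, sample_background
from .conservation import RESIDUE_GROUPS
from .core_io import Msa, Sequence, newick_string, write_fasta, write_tsv

logger = logging.getLogger("hhdscope.synthetic_data")

_GROUP_IDX = {g: np.array([AA_INDEX[a] for a in g]) for g in RESIDUE_GROUPS}

#: Shared conservation architecture of the planted superfamily, master
#: frame 1-78: hydrophobic core 7/11/27/61 plus the three stabilizing
#: pairs 30-69 (aromatic to cationic), 19-54 and 62-74 (salt bridges).
SHARED_CONSERVED: dict[int, str] = {
    7: "AVILM", 11: "AVILM", 27: "AVILM", 61: "AVILM",
    30: "FY", 69: "RKH",
    19: "ED", 54: "RKH",
    62: "RKH", 74: "ED",
}

#: The stabilizing pairs as planted, (colA, colB, groupA, groupB).
SHARED_PAIRS: frozenset[tuple[int, int, str, str]] = frozenset(
    {(30, 69, "FY", "RKH"), (19, 54, "ED", "RKH"), (62, 74, "RKH", "ED")}
)


class ParameterError(ValueError):
    pass


class GenerationError(RuntimeError):
    """Identity target unreachable after the allowed rate rescalings."""


@dataclass
class FamilySpec:
    """Specification of one planted domain family."""

    name: str
    n_seqs: int
    domain_length: int = 78
    conserved_positions: dict[int, str] = field(default_factory=dict)
    pair_positions: frozenset[tuple[int, int, str, str]] = frozenset()
    within_family_identity: float = 0.65
    truncate_after: int | None = None
    n_subfamilies: int = 1
    between_subfamily_identity: float | None = None
    #: 'random' gives a random join tree (identity gradients, correlated
    #: drift); 'star' makes members conditionally independent given the
    #: family root — the regime of a deep, dereplicated cluster, where
    #: unplanted columns drift below the conservation threshold.
    topology: str = "random"

    def __post_init__(self) -> None:
        if "__" in self.name or "." in self.name:
            raise ParameterError("family names may not contain '__' or '.'")
        if not 0 < self.within_family_identity <= 1:
            raise ParameterError("within_family_identity must be in (0, 1]")
        declared = set(self.conserved_positions) | {
            c for a, b, *_ in self.pair_positions for c in (a, b)
        }
        if any(not 1 <= c <= self.domain_length for c in declared):
            raise ParameterError(
                f"family {self.name}: conserved positions outside 1..{self.domain_length}"
            )
        if self.n_subfamilies > 1 and self.between_subfamily_identity is None:
            raise ParameterError("subfamilies require between_subfamily_identity")
        if self.topology not in ("random", "star"):
            raise ParameterError(f"unknown topology {self.topology!r}")

    @property
    def effective_conserved(self) -> dict[int, str]:
        """Conserved-position map including pair positions, clipped to length."""
        out = dict(self.conserved_positions)
        for a, b, ga, gb in self.pair_positions:
            out.setdefault(a, ga)
            out.setdefault(b, gb)
        limit = self.truncate_after or self.domain_length
        return {c: g for c, g in out.items() if c <= limit}


@dataclass
class TruthRow:
    protein_id: str
    family: str
    dom_start: int  # 1-based inclusive on the protein
    dom_end: int
    subfamily: str = ""
    member_id: str = ""  # id of the domain sequence in the family alignment


@dataclass
class TruthTable:
    """Planted truth for one simulated database."""

    rows: list[TruthRow]
    conserved_positions: dict[str, dict[int, str]]
    tree_newick: str

    def family_of(self) -> dict[str, str]:
        return {r.protein_id: r.family for r in self.rows}

    def write_tsv(self, path: str | Path) -> None:
        write_tsv(
            [r.__dict__ for r in self.rows],
            path,
            ["protein_id", "family", "dom_start", "dom_end", "subfamily", "member_id"],
        )


# ---------------------------------------------------------------------------
# generating tree


def generate_tree(
    n_families: int,
    n_seqs_per_family: int | list[int],
    seed: int,
    family_names: list[str] | None = None,
    n_subfamilies: dict[str, int] | None = None,
    star_families: set[str] | None = None,
) -> dendropy.Tree:
    """Random binary generating tree with monophyletic family clades.

    The first family is the outgroup, attached by the deepest branch (at
    the root). Edges carry a ``length_class`` attribute in
    {'intra', 'substem', 'backbone'} used by the identity calibration.
    """
    if n_families < 2:
        raise ParameterError("n_families must be >= 2")
    rng = np.random.default_rng([seed, 11])
    if isinstance(n_seqs_per_family, int):
        counts = [n_seqs_per_family] * n_families
    else:
        counts = list(n_seqs_per_family)
    names = family_names or [f"fam{k}" for k in range(n_families)]
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    n_subfamilies = n_subfamilies or {}
    star_families = star_families or set()

    def leaf(label: str) -> dendropy.Node:
        node = dendropy.Node()
        node.taxon = taxa.new_taxon(label)
        return node

    def join(a: dendropy.Node, b: dendropy.Node, scale: float, klass: str) -> dendropy.Node:
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        for child in (a, b):
            if klass == "intra":
                child.edge.length = float(rng.exponential(scale) + 0.02)
            else:
                # backbone and subfamily stems: jittered fixed lengths, so
                # every family pair is separated by a comparable path and
                # no two clades end up accidentally adjacent
                child.edge.length = float(scale * (0.75 + 0.5 * rng.random()))
            child.edge.length_class = klass
        return parent

    def random_subtree(labels: list[str], scale: float, klass: str) -> dendropy.Node:
        nodes = [leaf(lb) for lb in labels]
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            merged = join(nodes[i], nodes[j], scale, klass)
            nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [merged]
        return nodes[0]

    def family_clade(name: str, count: int) -> dendropy.Node:
        # intra edges are tagged per family so each family's within-clade
        # rate can be calibrated to its own identity target
        labels = [f"{name}__s{i}" for i in range(count)]
        k_sub = n_subfamilies.get(name, 1)
        if k_sub <= 1:
            root = random_subtree(labels, 0.15, f"intra:{name}")
        else:
            per = int(np.ceil(count / k_sub))
            subroots = []
            for j in range(k_sub):
                chunk = labels[j * per : (j + 1) * per]
                sub = random_subtree(
                    [f"{name}.sub{j}__{lb.split('__')[1]}" for lb in chunk],
                    0.15, f"intra:{name}",
                )
                subroots.append(sub)
            root = subroots[0]
            for sub in subroots[1:]:
                root = join(root, sub, 0.3, "substem")
        if name in star_families:
            # star regime: pendant edges carry essentially all divergence,
            # so leaves are conditionally independent given the clade root
            for node in root.preorder_iter():
                if node is root:
                    continue
                if node.edge.length_class.startswith("intra"):
                    node.edge.length = (
                        float(1.0 * (0.9 + 0.2 * rng.random()))
                        if node.is_leaf() else 1e-3
                    )
        root.family = name
        return root

    clades = [family_clade(names[k], counts[k]) for k in range(n_families)]
    ingroup = clades[1]
    for clade in clades[2:]:
        ingroup = join(ingroup, clade, 0.25, "backbone")
    root = join(clades[0], ingroup, 0.6, "backbone")
    tree.seed_node = root
    return tree


# ---------------------------------------------------------------------------
# sequence evolution


def _draw_root(length: int, conserved: dict[int, str], rng: np.random.Generator) -> np.ndarray:
    seq = rng.choice(len(AMINO_ACIDS), size=length, p=BACKGROUND)
    for col, group in conserved.items():
        seq[col - 1] = rng.choice(_GROUP_IDX[group])
    return seq


def _mutate(
    seq: np.ndarray,
    p_event: float,
    conserved: dict[int, str],
    rng: np.random.Generator,
) -> np.ndarray:
    """One branch of per-site resampling.

    The uniform draws and candidate targets are generated for every site
    regardless of ``p_event``, so increasing the rate only adds mutated
    sites (monotone coupling used by the calibration bisection).
    Conserved columns resample within their residue group only.
    """
    L = len(seq)
    u = rng.random(L)
    targets = rng.choice(len(AMINO_ACIDS), size=L, p=BACKGROUND)
    group_draws = rng.random(L)
    new = np.where(u < p_event, targets, seq)
    for col, group in conserved.items():
        idx = _GROUP_IDX[group]
        if u[col - 1] < p_event:
            new[col - 1] = idx[int(group_draws[col - 1] * len(idx))]
        else:
            new[col - 1] = seq[col - 1]
    return new


def _family_context(label: str) -> tuple[str, str]:
    """(family, subfamily) of a leaf label like 'fam.sub0__s3' or 'fam__s3'."""
    head = label.split("__")[0]
    if ".sub" in head:
        fam, sub = head.split(".sub")
        return fam, f"sub{sub}"
    return head, ""


def _evolve_tree(
    tree: dendropy.Tree,
    specs: dict[str, FamilySpec],
    scales: dict[str, float],
    rate: float,
    seed: int,
) -> dict[str, np.ndarray]:
    """Evolve one sequence per leaf down the generating tree.

    ``scales`` multiplies branch lengths per ``length_class``. Family
    clade roots (nodes carrying ``family``) force their family-specific
    conserved columns into the planted group before descending.
    """
    length = max(s.domain_length for s in specs.values())
    shared = {}
    for s in specs.values():
        shared.update({c: g for c, g in s.effective_conserved.items()})
    rng = np.random.default_rng([seed, 23])
    root_seq = _draw_root(length, SHARED_CONSERVED, rng)

    out: dict[str, np.ndarray] = {}

    def descend(node: dendropy.Node, seq: np.ndarray, conserved: dict[int, str]) -> None:
        fam = getattr(node, "family", None)
        if fam is not None:
            conserved = specs[fam].effective_conserved
            seq = seq.copy()
            for col, group in conserved.items():
                if seq[col - 1] not in _GROUP_IDX[group]:
                    seq[col - 1] = rng.choice(_GROUP_IDX[group])
        if node.is_leaf():
            out[node.taxon.label] = seq
            return
        for child in node.child_nodes():
            t = child.edge.length * scales.get(child.edge.length_class, 1.0)
            p = 1.0 - np.exp(-rate * t)
            descend(child, _mutate(seq, p, conserved, rng), conserved)

    descend(tree.seed_node, root_seq, SHARED_CONSERVED)
    return out


def _identity(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean(a == b))


def _mean_identity(pairs: list[tuple[np.ndarray, np.ndarray]]) -> float:
    return float(np.mean([_identity(a, b) for a, b in pairs]))


def _calibrate_scale(
    measure, target: float, lo: float = 1e-3, hi: float = 64.0,
    tol: float = 0.02, max_iter: int = 20,
) -> float:
    """Bisection on a branch-length scale so ``measure`` hits ``target``.

    ``measure(scale)`` must be monotone decreasing (more divergence at a
    larger scale); raises :class:`GenerationError` if the target stays
    out of reach by more than 5 percentage points.
    """
    if target >= 1.0:
        return 0.0  # identity 1 is exactly a zero substitution rate
    best_scale, best_err = 1.0, np.inf
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)
        obs = measure(mid)
        err = obs - target
        if abs(err) < abs(best_err):
            best_scale, best_err = mid, err
        if abs(err) <= tol:
            return mid
        if err > 0:  # identity too high -> more divergence
            lo = mid
        else:
            hi = mid
    if abs(best_err) > 0.05:
        raise GenerationError(
            f"identity target {target:.2f} unreachable (best error {best_err:+.3f})"
        )
    return best_scale


@dataclass
class EvolvedFamilies:
    """Aligned members per family plus the calibrated generating tree."""

    tree: dendropy.Tree
    alignments: dict[str, Msa]          # family -> alignment (truncation applied)
    subfamily: dict[str, str]           # member id -> subfamily label ('' if none)
    scales: dict[str, float]


def evolve_families(
    specs: list[FamilySpec],
    seed: int,
    between_family_identity: float = 0.22,
) -> EvolvedFamilies:
    """Evolve all families over one generating tree with calibrated rates.

    Calibration order: one within-clade scale per family (its mean
    within-family — or within-subfamily — identity), then the subfamily
    stem scale (mean cross-subfamily identity), then the backbone scale.
    The backbone is calibrated on the *closest* family pair (the maximum
    over family pairs of the mean cross-family identity), so
    ``between_family_identity`` is an upper level no family pair exceeds
    on average and thresholds strictly between the between/within levels
    separate all families. Each knob only affects its own identity level
    given the earlier ones, so sequential bisections suffice.
    """
    spec_map = {s.name: s for s in specs}
    names = [s.name for s in specs]
    n_sub = {s.name: s.n_subfamilies for s in specs if s.n_subfamilies > 1}
    stars = {s.name for s in specs if s.topology == "star"}
    tree = generate_tree(
        len(specs), [s.n_seqs for s in specs], seed, names, n_sub, stars
    )

    def realize(scales: dict[str, float]) -> dict[str, np.ndarray]:
        return _evolve_tree(tree, spec_map, scales, rate=1.0, seed=seed)

    def groups_of(seqs: dict[str, np.ndarray]):
        by_fam: dict[str, list[np.ndarray]] = {}
        by_sub: dict[tuple[str, str], list[np.ndarray]] = {}
        for label, arr in seqs.items():
            fam, sub = _family_context(label)
            by_fam.setdefault(fam, []).append(arr)
            by_sub.setdefault((fam, sub), []).append(arr)
        return by_fam, by_sub

    scales: dict[str, float] = {f"intra:{n}": 1.0 for n in names}
    scales["substem"] = 0.0
    scales["backbone"] = 0.0

    def within_measure_for(name: str):
        def measure(scale: float) -> float:
            trial = dict(scales)
            trial[f"intra:{name}"] = scale
            trial["substem"] = 0.0
            trial["backbone"] = 0.0
            _, by_sub = groups_of(realize(trial))
            vals = []
            for (fam, _), arrs in by_sub.items():
                if fam != name:
                    continue
                vals.extend(
                    _identity(arrs[i], arrs[j])
                    for i in range(len(arrs)) for j in range(i + 1, len(arrs))
                )
            return float(np.mean(vals)) if vals else float("nan")
        return measure

    for spec in specs:
        if spec.n_seqs < 2:
            continue  # a single-member family has no within identity
        scales[f"intra:{spec.name}"] = _calibrate_scale(
            within_measure_for(spec.name), spec.within_family_identity
        )

    sub_targets = [
        s.between_subfamily_identity for s in specs if s.n_subfamilies > 1
    ]
    if sub_targets:
        def substem_measure(scale: float) -> float:
            trial = dict(scales)
            trial["substem"] = scale
            trial["backbone"] = 0.0
            _, by_sub = groups_of(realize(trial))
            vals = []
            for fam in n_sub:
                subs = [arrs for (f, _), arrs in by_sub.items() if f == fam]
                for i in range(len(subs)):
                    for j in range(i + 1, len(subs)):
                        vals.extend(
                            _identity(a, b) for a in subs[i] for b in subs[j]
                        )
            return float(np.mean(vals))

        scales["substem"] = _calibrate_scale(
            substem_measure, float(np.mean(sub_targets))
        )

    def backbone_measure(scale: float) -> float:
        trial = dict(scales)
        trial["backbone"] = scale
        by_fam, _ = groups_of(realize(trial))
        fams = list(by_fam)
        pair_means = []
        rng = np.random.default_rng([seed, 31])
        for i in range(len(fams)):
            for j in range(i + 1, len(fams)):
                a_list, b_list = by_fam[fams[i]], by_fam[fams[j]]
                take = min(len(a_list), len(b_list), 16)
                ia = rng.choice(len(a_list), size=take, replace=False)
                ib = rng.choice(len(b_list), size=take, replace=False)
                pair_means.append(float(np.mean(
                    [_identity(a_list[k], b_list[m]) for k, m in zip(ia, ib)]
                )))
        return max(pair_means)

    scales["backbone"] = _calibrate_scale(backbone_measure, between_family_identity)
    seqs = realize(scales)

    alignments: dict[str, Msa] = {}
    subfamily: dict[str, str] = {}
    members: dict[str, list[Sequence]] = {name: [] for name in names}
    for label in sorted(seqs):
        fam, sub = _family_context(label)
        spec = spec_map[fam]
        arr = seqs[label]
        limit = spec.truncate_after or spec.domain_length
        residues = "".join(AMINO_ACIDS[i] for i in arr[:limit])
        member_id = label.replace(".", "_")
        members[fam].append(Sequence(member_id, residues, taxon=fam))
        subfamily[member_id] = sub
    for name in names:
        alignments[name] = Msa(members[name])
    return EvolvedFamilies(tree, alignments, subfamily, scales)


def evolve_family(spec: FamilySpec, seed: int) -> Msa:
    """Evolve a single family against a minimal two-family tree.

    Convenience wrapper used by tests and examples; the family of
    interest is evolved alongside a small outgroup clade and returned
    alone. Domains carry no indels, so the alignment is the sequences.
    """
    out = FamilySpec("auxoutgroup", n_seqs=max(3, spec.n_seqs // 4),
                     domain_length=spec.domain_length,
                     within_family_identity=spec.within_family_identity,
                     topology=spec.topology)
    ev = evolve_families([out, spec], seed=seed)
    return ev.alignments[spec.name]


# ---------------------------------------------------------------------------
# embedding into proteins


def embed_in_proteins(
    evolved: EvolvedFamilies,
    n_decoys: int,
    seed: int,
    flank_length_range: tuple[int, int] = (30, 120),
    two_domain_fraction: float = 0.05,
    decoy_length_range: tuple[int, int] = (150, 400),
) -> tuple[list[Sequence], TruthTable]:
    """Embed every domain instance into a longer protein.

    Flanks are i.i.d. background-composition peptides; a
    ``two_domain_fraction`` of family proteins carries a tandem second
    copy of its domain; ``n_decoys`` pure-background proteins are
    appended. Truth coordinates are 1-based inclusive and exact.
    """
    if not evolved.alignments:
        raise ParameterError("no families to embed")
    rng = np.random.default_rng([seed, 47])
    lo, hi = flank_length_range
    proteins: list[Sequence] = []
    rows: list[TruthRow] = []
    conserved = {}
    for fam, msa in evolved.alignments.items():
        for member in msa.members:
            domain = member.ungapped
            pid = f"prot_{member.id}"
            nflank = sample_background(rng, int(rng.integers(lo, hi + 1)))
            cflank = sample_background(rng, int(rng.integers(lo, hi + 1)))
            two = rng.random() < two_domain_fraction
            if two:
                linker = sample_background(rng, int(rng.integers(lo, hi + 1)))
                residues = nflank + domain + linker + domain + cflank
                s1 = len(nflank) + 1
                rows.append(TruthRow(pid, fam, s1, s1 + len(domain) - 1,
                                     evolved.subfamily.get(member.id, ""), member.id))
                s2 = len(nflank) + len(domain) + len(linker) + 1
                rows.append(TruthRow(pid, fam, s2, s2 + len(domain) - 1,
                                     evolved.subfamily.get(member.id, ""), member.id))
            else:
                residues = nflank + domain + cflank
                s1 = len(nflank) + 1
                rows.append(TruthRow(pid, fam, s1, s1 + len(domain) - 1,
                                     evolved.subfamily.get(member.id, ""), member.id))
            proteins.append(Sequence(pid, residues, taxon=fam))
    for k in range(n_decoys):
        length = int(rng.integers(decoy_length_range[0], decoy_length_range[1] + 1))
        proteins.append(Sequence(f"decoy_{k}", sample_background(rng, length)))
    truth = TruthTable(rows, conserved, newick_string(evolved.tree))
    return proteins, truth


# ---------------------------------------------------------------------------
# the default benchmark


def default_benchmark_specs(
    n_families: int = 5, n_seqs: int = 40
) -> list[FamilySpec]:
    """The study conditions used throughout the test-suite and examples.

    Five paralogous families of 40 members: a four-helix outgroup family
    truncated after column 60 (loses the fifth helix and with it the
    62-74 stabilizing pair), three ordinary five-helix families, and one
    family split into two subfamilies diverging at ~50% identity —
    emulating a subclass that surfaces only when the clustering
    inclusion threshold is raised past the mid-50s. Family-specific
    conserved columns come on top of the shared core architecture.
    """
    shared = dict(SHARED_CONSERVED)
    per_family_extra = [
        {},                                   # outgroup
        {15: "QN", 35: "G", 55: "TS"},
        {16: "P", 36: "ED", 56: "AVILM"},
        {14: "RKH", 34: "TS", 57: "QN"},
        {13: "ED", 33: "AVILM", 58: "G"},
    ]
    names = ["PAH_like", "HHD_A", "HHD_B", "HHD_C", "HHD_D"]
    specs = []
    for k in range(n_families):
        name = names[k] if k < len(names) else f"HHD_{k}"
        extra = per_family_extra[k] if k < len(per_family_extra) else {}
        conserved = {**shared, **extra}
        if k == 0:
            specs.append(FamilySpec(
                name, n_seqs, conserved_positions=conserved,
                pair_positions=SHARED_PAIRS, within_family_identity=0.65,
                truncate_after=60,
            ))
        elif name == "HHD_D":
            specs.append(FamilySpec(
                name, n_seqs, conserved_positions=conserved,
                pair_positions=SHARED_PAIRS, within_family_identity=0.78,
                n_subfamilies=2, between_subfamily_identity=0.50,
            ))
        else:
            specs.append(FamilySpec(
                name, n_seqs, conserved_positions=conserved,
                pair_positions=SHARED_PAIRS, within_family_identity=0.65,
            ))
    return specs


@dataclass
class Benchmark:
    """A fully realized synthetic study: database, truth and alignments."""

    specs: list[FamilySpec]
    evolved: EvolvedFamilies
    database: list[Sequence]
    truth: TruthTable
    seed_msa: Msa  # cross-family seed alignment for profile building

    @property
    def family_alignments(self) -> dict[str, Msa]:
        return self.evolved.alignments


def default_benchmark(
    seed: int = 42,
    n_families: int = 5,
    n_seqs: int = 40,
    n_decoys: int = 500,
    seed_members_per_family: int = 5,
) -> Benchmark:
    """Generate the default synthetic benchmark.

    The profile seed alignment takes ``seed_members_per_family`` members
    spread evenly across every family alignment (the truncated outgroup
    padded with end gaps), mirroring a curated superfamily seed whose
    known members span each family's diversity — including subfamilies.
    """
    specs = default_benchmark_specs(n_families, n_seqs)
    evolved = evolve_families(specs, seed=seed)
    database, truth = embed_in_proteins(evolved, n_decoys=n_decoys, seed=seed)
    truth.conserved_positions = {s.name: s.effective_conserved for s in specs}
    width = max(s.domain_length for s in specs)
    seed_members = []
    for spec in specs:
        members = evolved.alignments[spec.name].members
        take = np.linspace(0, len(members) - 1, seed_members_per_family).astype(int)
        for idx in sorted(set(take.tolist())):
            member = members[idx]
            residues = member.residues + "-" * (width - len(member.residues))
            seed_members.append(Sequence(member.id, residues, taxon=spec.name))
    return Benchmark(specs, evolved, database, truth, Msa(seed_members))


def write_benchmark(bench: Benchmark, outdir: str | Path) -> dict[str, Path]:
    """Write database FASTA, per-family alignments, truth TSV and tree."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"database": outdir / "database.fasta", "truth": outdir / "truth.tsv",
             "tree": outdir / "generating_tree.nwk", "seed_msa": outdir / "seed.afa"}
    write_fasta(bench.database, paths["database"])
    bench.truth.write_tsv(paths["truth"])
    paths["tree"].write_text(bench.truth.tree_newick + "\n")
    write_fasta(bench.seed_msa.members, paths["seed_msa"])
    for fam, msa in bench.family_alignments.items():
        p = outdir / f"family_{fam}.afa"
        write_fasta(msa.members, p)
        paths[f"family_{fam}"] = p
    return paths
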