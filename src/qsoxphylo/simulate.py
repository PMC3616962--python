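"""Synthetic two-domain enzyme families with fully known ground truth.

The generator emulates the statistical structure the comparative analysis
assumes: each protein is an N-terminal extension, a Trx oxidoreductase domain
(optionally followed by a non-catalytic Trx2 copy in flagged clades), a
length-constrained variable linker (default 20-35 residues), an Erv
sulfhydryl-oxidase domain, and a C-terminal extension.  Domains are built
from the extraction patterns themselves: literal and class positions, and the
fixed-offset scaffold preceding the first variable wildcard, are invariable;
the remaining wildcard positions evolve along a Yule tree under a named
substitution model.  The two cysteines of every motif site and the
clade-assigned interior dipeptides are held fixed, so motif content is
clade-structured by construction.  Indels are not simulated inside domains;
length variation comes only from linkers and terminal extensions, which keeps
the true alignment trivial.

Every family is validated before it is returned: the first pattern match of
each sequence must reproduce the planted coordinates exactly (the ground
truth would otherwise be ill-defined for pattern-based annotation).  Families
failing validation are regenerated from a derived sub-seed; the whole
procedure is deterministic in the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .align import Alignment
from .models import AA_ORDER, SubstitutionModel, get_model
from .patterns import AMINO_ACIDS, DomainPattern, erv_pattern, trx_pattern
from .trees import Node, Tree

GAP = "-"


class ConfigError(ValueError):
    """Invalid family configuration."""


# ---------------------------------------------------------------------------
# trees


def simulate_yule_tree(n_taxa: int, birth_rate: float, seed=0,
                       prefix: str = "t") -> Tree:
    """A pure-birth (Yule) tree with n_taxa uniquely labeled leaves.

    Waiting times between speciations are exponential with rate
    k * birth_rate for k extant lineages; the lineage that splits is chosen
    uniformly.  Branch lengths are strictly positive; the same seed yields a
    byte-identical newick string.
    """
    if n_taxa < 2:
        raise ConfigError("a Yule tree needs at least 2 taxa")
    if birth_rate <= 0:
        raise ConfigError("birth rate must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root = Node()
    active = [Node(length=0.0), Node(length=0.0)]
    root.children = list(active)
    while len(active) < n_taxa:
        k = len(active)
        dt = rng.exponential(1.0 / (k * birth_rate))
        for tip in active:
            tip.length += dt
        idx = int(rng.integers(k))
        parent = active.pop(idx)
        kids = [Node(length=0.0), Node(length=0.0)]
        parent.children = kids
        active.extend(kids)
    dt = rng.exponential(1.0 / (n_taxa * birth_rate))
    for tip in active:
        tip.length += dt
    width = max(2, len(str(n_taxa)))
    for i, leaf in enumerate(root.leaves(), start=1):
        leaf.name = f"{prefix}{i:0{width}d}"
    return Tree(root)


def balanced_tree(depth: int, branch_length: float = 0.5,
                  prefix: str = "t") -> Tree:
    """A complete binary tree with 2**depth leaves and equal branch lengths.

    Useful as a benchmark topology: every pair of leaves is separated by at
    least 2 * branch_length substitutions/site, so no two sequences simulated
    on it can stay near-identical by tree-shape accident.
    """
    if depth < 1:
        raise ConfigError("depth must be >= 1")

    def grow(d: int) -> Node:
        if d == 0:
            return Node(length=branch_length)
        return Node(length=branch_length, children=[grow(d - 1), grow(d - 1)])

    root = Node(children=[grow(depth - 1), grow(depth - 1)])
    width = max(2, len(str(2 ** depth)))
    for i, leaf in enumerate(root.leaves(), start=1):
        leaf.name = f"{prefix}{i:0{width}d}"
    return Tree(root)


def caterpillar_tree(labels: list[str], internal: float = 0.1,
                     terminal: float = 0.1) -> Tree:
    """A ladder (caterpillar) topology over *labels* in order.

    Every internal edge has length *internal*, so with moderate sequence
    length the topology is comfortably recoverable — a convenient planted
    truth for discordance benchmarks.
    """
    if len(labels) < 2:
        raise ConfigError("need at least 2 labels")
    node = Node(name=labels[-1], length=terminal)
    for lab in reversed(labels[1:-1]):
        node = Node(length=internal,
                    children=[Node(name=lab, length=terminal), node])
    root = Node(children=[Node(name=labels[0], length=terminal), node])
    node.length = internal
    return Tree(root)


# ---------------------------------------------------------------------------
# sequence evolution along a tree


def _sample_states(P: np.ndarray, parent: np.ndarray, rng) -> np.ndarray:
    u = rng.random(parent.size)
    cum = np.cumsum(P, axis=1)
    return (u[:, None] > cum[parent]).sum(axis=1)


def evolve_states(tree: Tree, n_sites: int, model: SubstitutionModel,
                  rng, rate: float = 1.0,
                  root_states: np.ndarray | None = None) -> dict[str, np.ndarray]:
    """Evolve integer site states down *tree*; returns leaf name -> states.

    Per branch of length b the per-site transition matrix is P(rate * b);
    sampling order is the tree's preorder, so results are seed-stable.
    """
    if root_states is None:
        root_states = rng.choice(20, size=n_sites, p=model.pi)
    out: dict[str, np.ndarray] = {}

    def walk(node: Node, states: np.ndarray):
        for c in node.children:
            t = rate * (c.length or 0.0)
            child = states if t == 0 else _sample_states(
                model.transition_matrix(t), states, rng)
            if c.is_leaf:
                out[c.name] = child
            walk(c, child.copy() if not c.is_leaf else child)

    walk(tree.root, root_states)
    return out


def simulate_alignment(tree: Tree, length: int, model="jtt", seed=0,
                       rate: float = 1.0,
                       invariable: dict[int, str] | None = None) -> Alignment:
    """Simulate an ungapped alignment of *length* columns along *tree*.

    *invariable* maps column index -> residue held fixed in every row
    (planted conserved sites).  Rows follow the tree's leaf order.
    """
    if isinstance(model, str):
        model = get_model(model)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    states = evolve_states(tree, length, model, rng, rate=rate)
    inv = invariable or {}
    for pos, res in inv.items():
        if not 0 <= pos < length:
            raise ConfigError(f"invariable position {pos} outside [0, {length})")
    ids, rows = [], []
    for name in tree.leaf_names():
        chars = [AA_ORDER[s] for s in states[name]]
        for pos, res in inv.items():
            chars[pos] = res
        ids.append(name)
        rows.append("".join(chars))
    return Alignment(ids, rows)


# ---------------------------------------------------------------------------
# domain layout from a pattern


@dataclass
class DomainLayout:
    """A concrete expansion of an extraction pattern into a fixed-length
    domain: element boundaries, invariable scaffold, and evolving sites."""

    pattern: DomainPattern
    length: int
    boundaries: list[int]              # element start offsets + final end
    pinned: dict[int, str]             # shared invariable scaffold
    free: list[int]                    # evolving positions
    captures: dict[str, tuple[int, int]]

    def capture_interior(self, label: str) -> list[int]:
        s, e = self.captures[label]
        return list(range(s + 1, e - 1))


def _class_representative(element_residues: frozenset, others: list[frozenset]) -> str:
    """Deterministic class member, preferring residues unique to this class
    (and avoiding 'C', reserved for motif cysteines)."""
    ordered = [c for c in AMINO_ACIDS if c in element_residues]
    for c in ordered:
        if c != "C" and not any(c in o for o in others):
            return c
    for c in ordered:
        if c != "C":
            return c
    return ordered[0]


def build_layout(pattern: DomainPattern, length: int, rng,
                 pi: np.ndarray, catalytic: bool = True) -> DomainLayout:
    """Expand *pattern* to a domain of *length* residues.

    Slack above the minimum span is shared among variable wildcards in
    proportion to their ranges (largest-remainder rounding, earlier wildcards
    first).  Literals, classes, and every position before the first variable
    wildcard are pinned (invariable); remaining wildcard positions are free.
    Non-catalytic layouts pin serine instead of cysteine at [CS]-type
    capture ends.
    """
    if not pattern.min_span <= length <= pattern.max_span:
        raise ConfigError(
            f"domain length {length} outside pattern span "
            f"[{pattern.min_span}, {pattern.max_span}]")
    elements = pattern.elements
    var_idx = [i for i, e in enumerate(elements) if e.variable]
    slack = length - pattern.min_span
    extra = {i: 0 for i in var_idx}
    if var_idx and slack:
        ranges = {i: elements[i].max_len - elements[i].min_len for i in var_idx}
        total = sum(ranges.values())
        shares = {i: int(slack * ranges[i] // total) for i in var_idx}
        rem = slack - sum(shares.values())
        for i in var_idx:
            if rem == 0:
                break
            room = ranges[i] - shares[i]
            take = min(room, rem)
            shares[i] += take
            rem -= take
        extra = shares
    boundaries = [0]
    for i, e in enumerate(elements):
        boundaries.append(boundaries[-1] + e.min_len + extra.get(i, 0))
    assert boundaries[-1] == length

    first_var = min(var_idx) if var_idx else len(elements)
    prefix_end = boundaries[first_var]  # scaffold: everything before it
    class_sets = [e.residues for e in elements if e.kind == "class"]
    pinned: dict[int, str] = {}
    free: list[int] = []
    for i, e in enumerate(elements):
        s, t = boundaries[i], boundaries[i + 1]
        if e.kind == "literal":
            pinned[s] = next(iter(e.residues))
        elif e.kind == "class":
            others = [c for c in class_sets if c is not e.residues]
            pinned[s] = _class_representative(e.residues, others)
        else:
            for p in range(s, t):
                if p < prefix_end:
                    pinned[p] = AA_ORDER[int(rng.choice(20, p=pi))]
                else:
                    free.append(p)
    captures = {lab: (boundaries[i], boundaries[j + 1])
                for lab, (i, j) in pattern.captures.items()}
    # motif capture ends are the cysteine positions; non-catalytic copies
    # (the Trx2 insertion) carry the pattern-permitted serine instead
    cys = "C" if catalytic else "S"
    for s, e in captures.values():
        pinned[s] = cys
        pinned[e - 1] = cys
    return DomainLayout(pattern, length, boundaries, pinned, free, captures)


# ---------------------------------------------------------------------------
# family configuration and truth


DEFAULT_CLADE_MOTIFS = {
    # emulating the lineage-structured motif interiors of the real family:
    # metazoan-like CGHC/CRDC, plant-like CPAC/CEEC, stramenopile-like CPHC
    "metazoa": {"trx_cxxc": "GH", "erv_cxxc": "RD", "ct_cxxc": "KQ"},
    "viridiplantae": {"trx_cxxc": "PA", "erv_cxxc": "EE", "ct_cxxc": "RN"},
    "stramenopiles": {"trx_cxxc": "PH", "erv_cxxc": "QE", "ct_cxxc": "NA"},
}

#: residue two positions upstream of the Trx-CXXC: Ser/Thr in metazoan-like
#: clades, His in plant-like ones (the family-discriminating position)
DEFAULT_CLADE_DISCRIMINANT = {
    "metazoa": "S",
    "viridiplantae": "H",
    "stramenopiles": "T",
}


@dataclass
class FamilyConfig:
    """Study conditions for one synthetic family."""

    n_taxa: int = 40
    birth_rate: float = 1.0
    tree_height: float = 0.5            # root-to-tip height after rescaling
    domain_lengths: tuple[int, int] = (70, 160)   # (Trx, Erv) residues
    linker_range: tuple[int, int] = (20, 35)
    terminal_extension_range: tuple[int, int] = (5, 15)
    clade_motifs: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_CLADE_MOTIFS.items()})
    clade_discriminant: dict = field(default_factory=lambda: dict(DEFAULT_CLADE_DISCRIMINANT))
    architecture: dict = field(default_factory=dict)   # clade -> Trx2 flag
    model: str = "jtt"
    rate_multipliers: tuple[float, float] = (1.0, 1.0)  # per-domain
    erv_tree: Tree | None = None        # discordant Erv topology (optional)
    seed: int = 0

    def validate(self) -> None:
        if self.n_taxa < 2:
            raise ConfigError("n_taxa must be >= 2")
        if self.birth_rate <= 0 or self.tree_height <= 0:
            raise ConfigError("rates must be positive")
        lo, hi = self.linker_range
        if lo < 0 or lo > hi:
            raise ConfigError("linker_range must satisfy 0 <= min <= max")
        lo, hi = self.terminal_extension_range
        if lo < 0 or lo > hi:
            raise ConfigError("terminal_extension_range must satisfy 0 <= min <= max")
        if any(r < 0 for r in self.rate_multipliers):
            raise ConfigError("rate multipliers must be >= 0")
        if not self.clade_motifs:
            raise ConfigError("at least one clade must be configured")
        if len(self.clade_motifs) > self.n_taxa:
            raise ConfigError("more clades than taxa")
        for clade, motifs in self.clade_motifs.items():
            for site in ("trx_cxxc", "erv_cxxc", "ct_cxxc"):
                m = motifs.get(site)
                if m is None:
                    raise ConfigError(f"clade {clade!r} missing motif for {site}")
                if len(m) != 2 or any(c not in AMINO_ACIDS for c in m):
                    raise ConfigError(f"motif interior {m!r} for {clade}/{site} "
                                      "must be a residue dipeptide")
        try:
            get_model(self.model)
        except ValueError as exc:
            raise ConfigError(str(exc)) from None


@dataclass
class SeqTruth:
    """Planted facts about one synthetic sequence (0-based half-open spans)."""

    seqid: str
    clade: str
    trx_span: tuple[int, int]
    erv_span: tuple[int, int]
    linker_span: tuple[int, int]
    trx2_span: tuple[int, int] | None
    motifs: dict[str, tuple[int, int, str]]   # label -> (start, end, string)
    discriminant: tuple[int, str]
    gene_model: list[int] | None = None
    introns: list[tuple[int, int]] | None = None   # (codon index, phase)


@dataclass
class SyntheticTruth:
    """Ground truth backing every test on a synthetic family."""

    tree_trx: Tree
    tree_erv: Tree
    per_seq: dict[str, SeqTruth]
    alignment: Alignment
    clades: dict[str, str]

    def clade_members(self, clade: str) -> list[str]:
        return [s for s, c in self.clades.items() if c == clade]


# ---------------------------------------------------------------------------
# family generation


def _assemble_domain(layout: DomainLayout, states: np.ndarray,
                     overrides: dict[int, str]) -> str:
    chars = [""] * layout.length
    for k, pos in enumerate(layout.free):
        chars[pos] = AA_ORDER[states[k]]
    for pos, res in layout.pinned.items():
        chars[pos] = res
    for pos, res in overrides.items():
        chars[pos] = res
    return "".join(chars)


def _random_segment(rng, pi: np.ndarray, length: int) -> str:
    return "".join(AA_ORDER[i] for i in rng.choice(20, size=length, p=pi))


def _generate_once(config: FamilyConfig, seed_seq: np.random.SeedSequence):
    rng = np.random.default_rng(seed_seq)
    model = get_model(config.model)
    pi = model.pi

    tree = simulate_yule_tree(config.n_taxa, config.birth_rate, rng)
    tree = tree.scaled(config.tree_height / tree.height())
    erv_tree = config.erv_tree if config.erv_tree is not None else tree
    if erv_tree.leaf_set != tree.leaf_set:
        raise ConfigError("erv_tree must share the leaf set with the Trx tree")

    clade_names = list(config.clade_motifs)
    groups = tree.k_deepest_clades(len(clade_names))
    if len(groups) < len(clade_names):
        raise ConfigError("tree too small for the configured number of clades")
    clades = {leaf: clade_names[g] for g, members in enumerate(groups)
              for leaf in members}

    trx_layout = build_layout(trx_pattern(), config.domain_lengths[0], rng, pi)
    erv_layout = build_layout(erv_pattern(), config.domain_lengths[1], rng, pi)
    any_trx2 = any(config.architecture.get(c, False) for c in clade_names)
    trx2_layout = None
    if any_trx2:
        trx2_layout = build_layout(trx_pattern(), config.domain_lengths[0], rng,
                                   pi, catalytic=False)

    r_trx, r_erv = config.rate_multipliers
    trx_states = evolve_states(tree, len(trx_layout.free), model, rng, rate=r_trx)
    erv_states = evolve_states(erv_tree, len(erv_layout.free), model, rng, rate=r_erv)
    trx2_states = (evolve_states(tree, len(trx2_layout.free), model, rng, rate=r_trx)
                   if any_trx2 else None)

    # per-clade overrides: motif interiors + the discriminant residue
    trx_over: dict[str, dict[int, str]] = {}
    erv_over: dict[str, dict[int, str]] = {}
    d_pos = trx_layout.captures["trx_cxxc"][0] - 2
    for clade in clade_names:
        motifs = config.clade_motifs[clade]
        ov = {}
        for pos, res in zip(trx_layout.capture_interior("trx_cxxc"),
                            motifs["trx_cxxc"]):
            ov[pos] = res
        ov[d_pos] = config.clade_discriminant.get(clade, "S")
        trx_over[clade] = ov
        ov = {}
        for lab in ("erv_cxxc", "ct_cxxc"):
            for pos, res in zip(erv_layout.capture_interior(lab), motifs[lab]):
                ov[pos] = res
        erv_over[clade] = ov

    ext_lo, ext_hi = config.terminal_extension_range
    link_lo, link_hi = config.linker_range
    leaf_order = tree.leaf_names()

    records: list[tuple[str, str]] = []
    per_seq: dict[str, SeqTruth] = {}
    parts_table: dict[str, dict[str, str]] = {}
    for leaf in leaf_order:
        clade = clades[leaf]
        trx2_on = config.architecture.get(clade, False)
        n_ext = _random_segment(rng, pi, int(rng.integers(ext_lo, ext_hi + 1)))
        linker = _random_segment(rng, pi, int(rng.integers(link_lo, link_hi + 1)))
        c_ext = _random_segment(rng, pi, int(rng.integers(ext_lo, ext_hi + 1)))
        trx_seq = _assemble_domain(trx_layout, trx_states[leaf], trx_over[clade])
        erv_seq = _assemble_domain(erv_layout, erv_states[leaf], erv_over[clade])
        trx2_seq = (_assemble_domain(trx2_layout, trx2_states[leaf], {})
                    if trx2_on else "")

        pos = len(n_ext)
        trx_span = (pos, pos + len(trx_seq)); pos = trx_span[1]
        trx2_span = None
        if trx2_on:
            trx2_span = (pos, pos + len(trx2_seq)); pos = trx2_span[1]
        linker_span = (pos, pos + len(linker)); pos = linker_span[1]
        erv_span = (pos, pos + len(erv_seq)); pos = erv_span[1]
        seq = n_ext + trx_seq + trx2_seq + linker + erv_seq + c_ext

        motifs: dict[str, tuple[int, int, str]] = {}
        for lab in ("trx_cxxc", "cx6_8c"):
            s, e = trx_layout.captures[lab]
            s, e = s + trx_span[0], e + trx_span[0]
            motifs[lab] = (s, e, seq[s:e])
        for lab in ("erv_cxxc", "ct_cxxc"):
            s, e = erv_layout.captures[lab]
            s, e = s + erv_span[0], e + erv_span[0]
            motifs[lab] = (s, e, seq[s:e])
        dp = trx_span[0] + d_pos
        per_seq[leaf] = SeqTruth(leaf, clade, trx_span, erv_span, linker_span,
                                 trx2_span, motifs, (dp, seq[dp]))
        records.append((leaf, seq))
        parts_table[leaf] = {"n": n_ext, "trx": trx_seq, "trx2": trx2_seq,
                             "link": linker, "erv": erv_seq, "c": c_ext}

    # true alignment: domains are indel-free blocks; extensions and linkers
    # are padded with gaps (N-extension right-justified, others left)
    w = {key: max(len(parts_table[l][key]) for l in leaf_order)
         for key in ("n", "trx", "trx2", "link", "erv", "c")}
    rows = []
    for leaf in leaf_order:
        p = parts_table[leaf]
        rows.append(GAP * (w["n"] - len(p["n"])) + p["n"]
                    + p["trx"]
                    + p["trx2"] + GAP * (w["trx2"] - len(p["trx2"]))
                    + p["link"] + GAP * (w["link"] - len(p["link"]))
                    + p["erv"]
                    + p["c"] + GAP * (w["c"] - len(p["c"])))
    truth = SyntheticTruth(tree, erv_tree, per_seq,
                           Alignment(list(leaf_order), rows), clades)
    return records, truth


def _validate_family(records, truth: SyntheticTruth) -> bool:
    from .motifs import annotate  # deferred import; no cycle at module load
    for seqid, seq in records:
        t = truth.per_seq[seqid]
        ann = annotate((seqid, seq))
        if ann.failure is not None:
            return False
        if ann.trx_span != t.trx_span or ann.erv_span != t.erv_span:
            return False
        for lab, (s, e, text) in t.motifs.items():
            if ann.motifs.get(lab) != (s, e, text):
                return False
    return True


def evolve_family(config: FamilyConfig, max_attempts: int = 25):
    """Generate one validated family: (records, truth).

    records is a list of (seqid, sequence); truth carries the planted trees,
    coordinates, motif strings and the gapped true alignment.  Generation is
    retried from derived sub-seeds until the pattern-based annotation of every
    sequence reproduces the planted coordinates (see module docstring).
    """
    config.validate()
    for attempt in range(max_attempts):
        ss = (np.random.SeedSequence(config.seed) if attempt == 0 else
              np.random.SeedSequence(config.seed, spawn_key=(attempt,)))
        records, truth = _generate_once(config, ss)
        if _validate_family(records, truth):
            return records, truth
    raise RuntimeError("could not generate a self-consistent family; "
                       "check the configuration")


# ---------------------------------------------------------------------------
# gene models


def generate_gene_models(truth: SyntheticTruth, introns_per_gene: int,
                         conserved_fraction: float, seed: int) -> SyntheticTruth:
    """Plant gene models (exon CDS lengths) with clade-conserved introns.

    A fraction *conserved_fraction* of each gene's introns sits at
    clade-characteristic anchor positions, expressed relative to a domain
    start so that every member of the clade carries the intron at the same
    column of the true alignment; anchors are drawn without replacement from
    a pool shared by all clades, so different clades never share an anchor.
    The remaining introns are placed uniformly at random per gene.  Exon CDS
    lengths sum to 3 * (protein length) + 3 (stop codon in the last exon).
    """
    if introns_per_gene < 0:
        raise ConfigError("introns_per_gene must be >= 0")
    if not 0.0 <= conserved_fraction <= 1.0:
        raise ConfigError("conserved_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_cons = int(round(conserved_fraction * introns_per_gene))
    clade_names = sorted({t.clade for t in truth.per_seq.values()})

    # shared anchor pool: (domain, codon offset within domain, phase)
    any_t = next(iter(truth.per_seq.values()))
    len_trx = any_t.trx_span[1] - any_t.trx_span[0]
    len_erv = any_t.erv_span[1] - any_t.erv_span[0]
    pool = [("trx", off) for off in range(1, len_trx - 1)]
    pool += [("erv", off) for off in range(1, len_erv - 1)]
    order = rng.permutation(len(pool))
    cursor = 0
    anchors: dict[str, list[tuple[str, int, int]]] = {}
    for clade in clade_names:
        picks = []
        for _ in range(n_cons):
            dom, off = pool[order[cursor]]
            cursor += 1
            picks.append((dom, off, int(rng.integers(0, 3))))
        anchors[clade] = sorted(picks, key=lambda a: (a[0], a[1]))

    for seqid in truth.alignment.ids:
        t = truth.per_seq[seqid]
        L = len(truth.alignment.degapped(seqid))
        cuts: set[int] = set()
        positions: list[tuple[int, int]] = []
        for dom, off, phase in anchors[t.clade]:
            start = t.trx_span[0] if dom == "trx" else t.erv_span[0]
            codon = start + off
            c = 3 * codon + phase
            if 0 < c < 3 * L and c not in cuts:
                cuts.add(c)
                positions.append((codon, phase))
        while len(positions) < introns_per_gene:
            codon = int(rng.integers(1, L - 1))
            phase = int(rng.integers(0, 3))
            c = 3 * codon + phase
            if c in cuts:
                continue
            cuts.add(c)
            positions.append((codon, phase))
        offsets = sorted(cuts)
        bounds = [0] + offsets + [3 * L + 3]
        t.gene_model = [b - a for a, b in zip(bounds, bounds[1:])]
        t.introns = sorted(positions, key=lambda p: 3 * p[0] + p[1])
    return truth


# ---------------------------------------------------------------------------
# writers


def write_family(records, truth: SyntheticTruth, outdir) -> dict[str, str]:
    """Write FASTA, newick trees and TSV truth tables; returns path map."""
    import os

    from .align import write_fasta
    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def p(name):
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    write_fasta(records, p("family.fasta"))
    truth.alignment.to_fasta(p("true_alignment.fasta"))
    with open(p("tree_trx.nwk"), "w") as fh:
        fh.write(truth.tree_trx.newick() + "\n")
    with open(p("tree_erv.nwk"), "w") as fh:
        fh.write(truth.tree_erv.newick() + "\n")
    with open(p("clades.tsv"), "w") as fh:
        fh.write("seqid\tclade\n")
        for sid, clade in truth.clades.items():
            fh.write(f"{sid}\t{clade}\n")
    with open(p("domains.tsv"), "w") as fh:
        fh.write("seqid\tstart\tend\tfeature\n")
        for sid, t in truth.per_seq.items():
            rows = [(t.trx_span, "trx"), (t.linker_span, "linker"),
                    (t.erv_span, "erv")]
            if t.trx2_span:
                rows.insert(1, (t.trx2_span, "trx2"))
            for (s, e), feat in rows:
                fh.write(f"{sid}\t{s}\t{e}\t{feat}\n")
            for lab, (s, e, text) in t.motifs.items():
                fh.write(f"{sid}\t{s}\t{e}\t{lab}\n")
    if any(t.gene_model for t in truth.per_seq.values()):
        with open(p("gene_models.tsv"), "w") as fh:
            fh.write("seqid\texon_cds_lengths\n")
            for sid, t in truth.per_seq.items():
                if t.gene_model:
                    fh.write(f"{sid}\t{','.join(map(str, t.gene_model))}\n")
    return paths
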