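import numpy as np
import pytest

import pleiostrat as ps


def random_newick(rng: np.random.Generator, n_leaves: int, allow_polytomy: bool = True) -> str:
    """Random rooted topology over sp0..sp{n-1}, with occasional polytomies."""
    nodes: list[str] = [f"sp{i}" for i in range(n_leaves)]
    while len(nodes) > 1:
        hi = min(len(nodes), 4 if allow_polytomy else 2)
        k = int(rng.integers(2, hi + 1)) if hi > 2 else 2
        idx = sorted(rng.choice(len(nodes), size=k, replace=False), reverse=True)
        picked = [nodes.pop(i) for i in idx]
        nodes.append("(" + ",".join(picked) + ")")
    return nodes[0] + ";"


def random_groups(
    rng: np.random.Generator,
    species: list[str],
    focal: str,
    n_genes: int,
    p_offtree: float = 0.1,
) -> ps.OrthologGroupSet:
    """Random ortholog groups; every gene is a focal gene, sometimes in
    several groups, with occasional off-tree member species."""
    groups: dict[str, set[tuple[str, str]]] = {}
    gid = 0
    for i in range(n_genes):
        gene = f"g{i}"
        for _ in range(int(rng.integers(1, 3))):
            members = {(focal, gene)}
            for _ in range(int(rng.integers(0, 4))):
                if rng.random() < p_offtree:
                    sp = f"offtree{int(rng.integers(5))}"
                else:
                    sp = species[int(rng.integers(len(species)))]
                members.add((sp, f"{gene}@{sp}"))
            groups[f"og{gid}"] = members
            gid += 1
    return ps.OrthologGroupSet(groups={k: frozenset(v) for k, v in groups.items()})


def oracle_depths(tree: ps.SpeciesTree, focal: str) -> dict[str, int]:
    """Brute-force MRCA depths: intersect full root-to-leaf node paths."""
    focal_path = set(tree.path_to_root(tree.node_of(focal)))
    out = {}
    for leaf in tree.leaves:
        common = focal_path & set(tree.path_to_root(leaf))
        out[tree.leaf_label[leaf]] = max(tree.depth[n] for n in common)
    return out


def oracle_ages(groups: ps.OrthologGroupSet, depths: dict[str, int], focal: str) -> dict[str, int]:
    """Brute force: enumerate every (gene, species) incidence, take min depth."""
    seen: dict[str, list[int]] = {}
    for members in groups.groups.values():
        focal_genes = [g for sp, g in members if sp == focal]
        for gene in focal_genes:
            for sp, _ in members:
                if sp in depths:
                    seen.setdefault(gene, []).append(depths[sp])
    return {g: min(ds) for g, ds in seen.items() if ds}


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    """One small synthetic bundle (files on disk) shared across tests."""
    cfg = ps.SyntheticConfig(seed=11, n_genes=400)
    d = tmp_path_factory.mktemp("bundle")
    bundle = ps.generate(cfg, out_dir=d)
    return cfg, d, bundle


@pytest.fixture(scope="session")
def pipeline_result(bundle_dir):
    cfg, d, _bundle = bundle_dir
    rc = ps.RunConfig(
        tree=str(d / "tree.nwk"), orthologs=str(d / "orthologs.tsv"),
        obo=str(d / "go.obo"), annotations=str(d / "annotations.tsv"),
        ppi=str(d / "ppi.tsv"), paralogs=str(d / "paralogs.tsv"),
        focal=cfg.focal, bin_threshold=50, min_genes=10,
        bootstrap_B=500, seed=cfg.seed,
    )
    return ps.run_all(rc)
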