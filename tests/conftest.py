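import pytest

from lepkaryo import infer, simulate


@pytest.fixture(scope="session")
def small_sim():
    """12-tip, 8-element simulation with 4 scripted simple events."""
    tree = simulate.simulate_tree(12, seed=2)
    outgroup = simulate.basal_outgroup(tree)
    ancestor = simulate.simulate_ancestral_genome(
        8, counts=[60, 50, 45, 40, 40, 38, 36, 30], seed=0, sex_index=7)
    script = simulate.random_simple_script(tree, ancestor, 4, seed=5,
                                           outgroup_tips=outgroup)
    tables, truth = simulate.evolve_genomes(
        tree, ancestor, simulate.EvolutionParams(seed=1), script=script)
    return {
        "tree": tree,
        "outgroup": outgroup,
        "ancestor": ancestor,
        "script": script,
        "tables": tables,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def small_root(small_sim):
    """Root linkage groups inferred from the small simulation, with
    element names matched to the generating ancestor."""
    sim = small_sim
    results, events, root_id = infer.infer_algs(
        sim["tables"], sim["tree"], infer.InferenceParams(),
        outgroup_tips=sim["outgroup"])
    root = results[root_id]
    sex = frozenset(o for label, ids, _ in sim["ancestor"].elements
                    if label == "MZ" for o in ids)
    mapping = infer.name_elements(root, sex)
    return infer.relabel(root, mapping)
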