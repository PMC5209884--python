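import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=60, deadline=None)
settings.load_profile("suite")

from bdxo.fixtures import default_registry
from bdxo.model import (
    IdFactory,
    InstanceGraph,
    PersonRecord,
    Population,
    Sample,
    build_tests_execution,
    record_tests_results,
)


@pytest.fixture
def registry():
    return default_registry()


@pytest.fixture
def ids():
    return IdFactory()


@pytest.fixture
def graph():
    return InstanceGraph()


def make_study(graph, ids, registry, *, pop_id, parent_id, index_id, reference_id,
               n_ref_pos, n_index_pos_of_ref_pos, n_ref_neg=0, n_index_pos_of_ref_neg=0):
    """Build one complete study (population, sample, execution, table) in the graph.

    The first ``n_ref_pos`` members are reference-positive, of whom the
    first ``n_index_pos_of_ref_pos`` are also index-positive; analogous for
    the reference-negatives.
    """
    n = n_ref_pos + n_ref_neg
    members = [PersonRecord(id=f"{pop_id}_m{i}", diseased=i < n_ref_pos) for i in range(n)]
    pop = Population(id=pop_id, members=members, parent_id=parent_id)
    graph.add_node(pop)
    for m in members:
        graph.add_node(m)
        graph.add_edge(m.id, "part_of", pop.id)
    sample = Sample(id=ids.mint("s"), population_id=pop.id, member_ids=[m.id for m in members])
    graph.add_node(sample)
    graph.add_edge(sample.id, "part_of", pop.id)
    results = {}
    for i, m in enumerate(members):
        if i < n_ref_pos:
            index_pos = i < n_index_pos_of_ref_pos
            results[m.id] = ("positive" if index_pos else "negative", "positive")
        else:
            j = i - n_ref_pos
            index_pos = j < n_index_pos_of_ref_neg
            results[m.id] = ("positive" if index_pos else "negative", "negative")
    execution = build_tests_execution(
        sample, registry.tests[index_id], registry.tests[reference_id], results,
        graph=graph, ids=ids,
    )
    table = record_tests_results(execution, graph=graph, ids=ids)
    return pop, sample, execution, table
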