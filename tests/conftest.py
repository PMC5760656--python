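import pytest

import pirna_profiler as pp
from pirna_profiler.annotate import ReadAnnotation
from pirna_profiler.io_preprocess import length_filter, select_mirna_proxy


@pytest.fixture(scope="session")
def desk_scenario():
    """Scaled-down study scenario: 20 clusters, 50k window reads, 5'-sparing KO."""
    return pp.ScenarioConfig.desk(seed=11)


@pytest.fixture(scope="session")
def desk_sim(desk_scenario):
    reference, wt, ko = pp.simulate_pair(desk_scenario)
    return reference, wt, ko


@pytest.fixture(scope="session")
def desk_annotated(desk_scenario, desk_sim):
    """Reference, hierarchy, and annotated WT/KO libraries for the desk pair."""
    reference, wt, ko = desk_sim
    hierarchy = reference.to_hierarchy()
    libs = {}
    for label, sim in (("wt", wt), ("ko", ko)):
        window = length_filter(sim.reads, 24, 32)
        mirna = select_mirna_proxy(sim.reads)
        libs[label] = pp.annotate_sequential(
            window, hierarchy, max_mismatch=1, mirna_count=len(mirna), source="total"
        )
    return reference, hierarchy, libs["wt"], libs["ko"]


def make_library(assignments, mirna_count=100, digest="test"):
    """Hand-build an AnnotatedLibrary from (category, target, start) tuples."""
    annotations = [
        ReadAnnotation(
            read_id=f"r{i}",
            category=cat,
            target_name=target,
            start=start,
            strand="sense" if target else None,
            mismatches=0 if target else None,
        )
        for i, (cat, target, start) in enumerate(assignments)
    ]
    return pp.AnnotatedLibrary(
        annotations=annotations,
        mirna_count=mirna_count,
        total_window_reads=len(annotations),
        params_digest=digest,
    )


@pytest.fixture
def toy_hierarchy():
    return pp.CategoryHierarchy(
        [
            ("piRNA_clusters", {"clusterA": "ACGTACGTACGTACGTACGTACGTACGT"}),
            ("coding_RNA", {"gene1": "ACGTACGTACGTACGTACGTACGTACGTTTTT"}),
        ]
    )
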