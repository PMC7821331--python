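"""Shared fixtures: a hand-written taxonomy and a cached mock-community run."""

from __future__ import annotations

import numpy as np
import pytest

from longmeta import pipeline
from longmeta.taxonomy import TaxonomyTree

# Hand-written ranked tree with a fish lineage, a water-lily genus with two
# congeners, a sedge genus with a single regional species, and an unranked
# intermediate clade (Esocoidei).
FIXTURE_TAXONOMY_TSV = """\
taxon_id\tparent_id\trank\tname\tnotes
1\t\troot\troot\t
2\t1\tsuperkingdom\tEukaryota\t
3\t2\tkingdom\tMetazoa\t
4\t3\tphylum\tChordata\t
5\t4\tclass\tActinopterygii\t
6\t5\torder\tEsociformes\t
60\t6\tno rank\tEsocoidei\t
7\t60\tfamily\tEsocidae\t
8\t7\tgenus\tEsox\t
9\t8\tspecies\tEsox lucius\t
10\t5\torder\tSalmoniformes\t
11\t10\tfamily\tSalmonidae\t
12\t11\tgenus\tOncorhynchus\t
13\t12\tspecies\tOncorhynchus mykiss\t
14\t2\tkingdom\tViridiplantae\t
15\t14\tphylum\tStreptophyta\t
16\t15\tclass\tMagnoliopsida\t
17\t16\torder\tNymphaeales\t
18\t17\tfamily\tNymphaeaceae\t
19\t18\tgenus\tNymphaea\t
20\t19\tspecies\tNymphaea alba\t
21\t19\tspecies\tNymphaea candida\t
22\t16\torder\tPoales\t
23\t22\tfamily\tCyperaceae\t
24\t23\tgenus\tCladium\t
25\t24\tspecies\tCladium mariscus\t
26\t3\tphylum\tArthropoda\t
27\t26\tclass\tInsecta\t
28\t27\torder\tDiptera\t
29\t28\tfamily\tChironomidae\t
30\t29\tgenus\tChironomus\t
31\t30\tspecies\tChironomus salinarius\t
"""


@pytest.fixture(scope="session")
def fixture_tree(tmp_path_factory) -> TaxonomyTree:
    path = tmp_path_factory.mktemp("tax") / "taxonomy.tsv"
    path.write_text(FIXTURE_TAXONOMY_TSV)
    return TaxonomyTree.from_tsv(path)


@pytest.fixture(scope="session")
def panel():
    from longmeta.pcr import load_panel

    return load_panel()


@pytest.fixture(scope="session")
def mc1_world():
    return pipeline.build_world(pipeline.MC1_MEMBERS, seed=1)


@pytest.fixture(scope="session")
def mc1_result(mc1_world):
    """One full end-to-end mock-community run, shared across tests."""
    spec = pipeline.community_spec(
        mc1_world, {name: 1.0 for name, _ in pipeline.MC1_MEMBERS}
    )
    return pipeline.run_sample(mc1_world, spec, seed=1, sample_id="MC1")


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
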