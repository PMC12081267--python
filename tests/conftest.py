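import numpy as np
import pytest

import actscreen as acts


@pytest.fixture(scope="session")
def minimal_bundle(tmp_path_factory):
    """One generated minimal cohort bundle, written to disk, shared read-only."""
    out = tmp_path_factory.mktemp("cohort")
    return acts.generate_cohort(acts.minimal_config(20240), out_dir=out)


@pytest.fixture(scope="session")
def minimal_screen(minimal_bundle):
    b = minimal_bundle
    return acts.screen(
        b.paths["vcf"], b.paths["clinvar"], b.paths["rules"], b.paths["reference"]
    )


def findings_as_tuples(findings):
    return {
        (f.individual_id, f.gene_symbol, tuple(sorted(str(v) for v in f.variants)), f.zygosity_pattern)
        for f in findings
    }


def truth_as_tuples(truth):
    return {(i, g, tuple(sorted(vs)), z) for i, g, vs, z in truth.findings}
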