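"""The packaged hip-arthroplasty extraction corpus.

Three systematic reviews (a BMJ review, a Cochrane review and an HTA
report, the latter acting as reference standard) extracted binary event
data for dislocation, 1-year mortality and revision from the same set of
randomised trials of total hip arthroplasty (THA) versus hemiarthroplasty
(HA).  The corpus stores every extracted cell, including explicit
not-reported (NR) markers, the variable-level error/selection annotation
layer, and one documented analysis exclusion.
"""

from importlib import resources

from .io import read_corpus
from .types import AuditCorpus

REFERENCE_REVIEW = "HTA"


def fixture_path():
    """Filesystem path of the packaged corpus directory."""
    return resources.files("extraudit").joinpath("data/fixture")


def load_fixture_corpus() -> AuditCorpus:
    """Load the packaged three-review hip-arthroplasty corpus."""
    with resources.as_file(fixture_path()) as path:
        return read_corpus(path, format="csv")
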