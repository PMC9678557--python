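import numpy as np
import pytest

from tonguemetrics.stats import ContingencyTable2x2

# observed exposure counts (cases then controls, out of 40 each) from the
# study's demographics table; used as golden inputs throughout
GREASY = ContingencyTable2x2(a=38, b=6, c=2, d=34)
THICK = ContingencyTable2x2(a=34, b=5, c=6, d=35)
TOOTH = ContingencyTable2x2(a=15, b=6, c=25, d=34)
WHITE = ContingencyTable2x2(a=32, b=7, c=8, d=33)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
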