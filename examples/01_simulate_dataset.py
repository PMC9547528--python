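"""Simulate a small two-subgenome genome and inspect what was planted.

Builds a toy paleotetraploid dataset (two 10 Mb chromosomes per subgenome)
with biased gene loss, region-dependent substitution rates, expression
dominance and biased ACR retention, then prints the retention bookkeeping.
"""

import json
import tempfile
from pathlib import Path

from subfrac.config import SimConfig
from subfrac.synthetic import generate_dataset

with tempfile.TemporaryDirectory() as tmp:
    config = SimConfig(seed=11, chrom_length=10_000_000)
    manifest = generate_dataset(config, tmp)

    print(f"ancestral genes : {manifest['n_ancestral_genes']}")
    print(f"retained pairs  : {manifest['n_pairs']}")
    print(f"maize1 singletons (maize2 copy lost): {manifest['n_singleton_m1']}")
    print(f"maize2 singletons (maize1 copy lost): {manifest['n_singleton_m2']}")
    truth = json.loads((Path(tmp) / "truth.json").read_text())
    print(f"planted pericentromere: {truth['peri_band']} bp")
    print(f"files written   : {len(manifest['files'])}")

# The singleton imbalance (maize1 singletons >> maize2 singletons) is the
# planted biased fractionation: the recessive subgenome loses more copies,
# so more surviving genes have their maize2 partner missing.
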