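"""Generate the synthetic two-design experiment.

Emits the consensus FASTA, both probe-design tables, the ground-truth ledger
and the raw intensity matrices (5 tissues x 2 replicates per design) under
results/analysis/.
"""

import pandas as pd

from common import OUTDIR, runner

if __name__ == "__main__":
    r = runner()
    r.simulate()
    r.write_manifest()
    ledger = pd.read_csv(f"{OUTDIR}/ledger.tsv", sep="\t")
    print(r.log[-1])
    print("probe categories:")
    print(ledger["category"].value_counts().to_string())
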