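"""Quantile-normalize each design's intensities within replicate pairs.

Arrays sharing (platform, tissue) are forced onto a common distribution;
writes values_design{A,B}_norm.tsv.
"""

from common import runner

if __name__ == "__main__":
    r = runner()
    r.normalize()
    r.write_manifest()
    print(r.log[-1])
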