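"""Recompute hub calls from the bundled published centrality rankings.

For each stage network of the colorectal-cancer study conditions this
package targets, the top-15 genes by betweenness, closeness and bottleneck
centrality are bundled as reference data.  Intersecting the three columns
yields the consensus hubs; intersecting those with the stage's novel
drivers yields the hub-driver genes.
"""

from stagenet import verify_tables
from stagenet.reference import REFERENCE_STAGES, load_driver_hubs, load_rankings

for stage in REFERENCE_STAGES:
    res = verify_tables(load_rankings(stage), load_driver_hubs(stage))
    print(f"stage {stage}:")
    print(f"  consensus hubs ({len(res.hubs)}): "
          + ", ".join(sorted(res.hubs)))
    print(f"  hub drivers ({len(res.hub_driver_genes)}): "
          + ", ".join(sorted(res.hub_driver_genes)))
    print(f"  non-driver hubs ({len(res.non_driver_hubs)}): "
          + ", ".join(sorted(res.non_driver_hubs)))

# Expected: 11/10/10 consensus hubs for stages II/III/IV, of which 3/4/3
# are also stage-specific novel drivers (e.g. DYNC1H1, GRIN2A, GRM1 for
# stage II) and 8/6/7 are central but non-driver genes.
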