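"""Score a miRNA against a transcript carrying a planted target site.

Builds a random transcript, implants a site with one core mismatch and one
G:U wobble, and runs the weighted-complementarity search.
"""

from mircleave import find_sites
from mircleave.synthetic import gen_mirnas, gen_transcriptome, implant_site
from mircleave.target_prediction import PairState

mirna = gen_mirnas(1, 21, seed=1)[0]
transcript = gen_transcriptome(1, (600, 600), 0.45, seed=2)[0]
transcript, truth, _ = implant_site(
    transcript, mirna, 200, edits=[(5, PairState.MISMATCH), (16, PairState.MISMATCH)]
)

for site in find_sites(mirna, transcript):
    print(
        f"{site.mirna_id} -> {site.transcript_id}  range {site.start}-{site.end}  "
        f"score {site.score:g}  cleavage at {site.cleavage_position}"
    )
print(
    "# score sums pairing penalties (mismatch 1, G:U 0.5, doubled at miRNA "
    "positions 2-13); the cleavage site is the base paired to miRNA nt 10"
)
print(f"# planted truth: score {truth.expected_score:g}, cleavage {truth.cleavage_position}")
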