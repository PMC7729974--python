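"""In-silico digestion: could FU-specific peptides be degraded in AF?

Each peptide is scanned bond by bond against simplified specificity tables
for pepsin, trypsin, chymotrypsin and Arg-C proteinase. A peptide with at
least one internal cleavage site under any enzyme is called degradable —
one explanation for why a peptide seen in fetal urine is absent from
amniotic fluid.
"""

from amniopep import AF_PANEL, cleavage_sites, degradable

peptides = {
    "collagen-like": "GPAGKDGEAGAQGPPGPAGPAGER",
    "poly-glycine": "GGGGGGGG",
    "aromatic-rich": "GAFYWAG",
}

for name, seq in peptides.items():
    deg, counts = degradable(seq, AF_PANEL)
    verdict = "degradable" if deg else "resistant"
    detail = ", ".join(f"{enz}: {n}" for enz, n in counts.items())
    print(f"{name:14} {verdict:10} ({detail})")

sites = cleavage_sites("GPAGKDGEAGAQGPPGPAGPAGER", "trypsin")
print(f"\ntrypsin cuts the collagen-like peptide after bond index(es) {sites} "
      "(0-based bond after residue i)")
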