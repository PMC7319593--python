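>synAcr_1 synthetic stand-in for an experimentally validated anti-CRISPR (placeholder list; replace with a curated FASTA for real use)
MKTLSEAWENCEAFAKEACRPRTEINNMADEFRTESTINGNLYDNTSEAR
CHFRTHISINREALDATAMKVL
>synAcr_2 synthetic stand-in entry
MSYNTHETICACRENTRYTWNTHISFILEESISTSNLYSTHE
KNWNLISTFILTERCANVEESERCISED
>synAcr_3 synthetic stand-in entry
MPLACEHLDERSEAVENCEFRTESTINGTHEKNWNANTICRISPRFILTER
PATHWAYNTAREALPRTEIN
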