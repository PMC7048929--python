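consequence	impact	coding
stop_gained	HIGH	True
stop_lost	HIGH	True
start_lost	HIGH	True
frameshift_variant	HIGH	True
splice_donor_variant	HIGH	False
splice_acceptor_variant	HIGH	False
transcript_ablation	HIGH	True
missense_variant	MEDIUM	True
inframe_deletion	MEDIUM	True
inframe_insertion	MEDIUM	True
protein_altering_variant	MEDIUM	True
splice_region_variant	LOW	False
synonymous_variant	LOW	True
stop_retained_variant	LOW	True
start_retained_variant	LOW	True
incomplete_terminal_codon_variant	LOW	True
intron_variant	MODIFIER	False
intergenic_variant	MODIFIER	False
upstream_gene_variant	MODIFIER	False
downstream_gene_variant	MODIFIER	False
5_prime_UTR_variant	MODIFIER	False
3_prime_UTR_variant	MODIFIER	False
non_coding_transcript_exon_variant	MODIFIER	False
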