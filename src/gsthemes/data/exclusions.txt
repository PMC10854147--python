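# Default word-exclusion list for gene-set name/description text mining.
# One lowercase token per line; '#' starts a comment.  These are database
# prefixes/suffixes and bookkeeping tokens commonly used to name gene-sets,
# carrying no biological meaning.  Informative generic words (pathway,
# signaling, process, regulation, ...) are deliberately NOT excluded.
# Replace via the exclusions argument / --exclusions flag.
kegg
reactome
hallmark
wikipathways
biocarta
pid
naba
sa
st
go
gobp
gocc
gomf
hp
wp
msigdb
gsea
module
geneset
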