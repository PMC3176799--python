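CCS1:
  clade: Rhodobacterales
  genome_gc_percent: 62
  matrix_clade: Roseobacter clade
  organism: Jannaschia sp. CCS1
  outgroup: false
  pgc_gc_percent: 62
DFL12:
  clade: Rhodobacterales
  genome_gc_percent: 65
  matrix_clade: Roseobacter clade
  organism: Dinoroseobacter shibae DFL 12
  outgroup: false
  pgc_gc_percent: 67
HTCC2080:
  clade: NOR5/OM60
  genome_gc_percent: 51
  matrix_clade: NOR5
  organism: Gammaproteobacterium HTCC2080
  outgroup: false
  pgc_gc_percent: 53
JL354:
  clade: Sphingomonadales
  genome_gc_percent: 65
  matrix_clade: Citromicrobium JL354
  organism: Citromicrobium sp. JL354
  outgroup: false
  pgc_gc_percent: 67
KT71:
  clade: NOR5/OM60
  genome_gc_percent: 58
  matrix_clade: NOR5
  organism: Congregibacter litoralis KT71
  outgroup: false
  pgc_gc_percent: 59
NAP1:
  clade: Sphingomonadales
  genome_gc_percent: 61
  matrix_clade: Erythrobacter NAP1
  organism: Erythrobacter sp. NAP1
  outgroup: false
  pgc_gc_percent: 62
OCh114:
  clade: Rhodobacterales
  genome_gc_percent: 58
  matrix_clade: Roseobacter clade
  organism: Roseobacter denitrificans OCh 114
  outgroup: false
  pgc_gc_percent: 60
Och149:
  clade: Rhodobacterales
  genome_gc_percent: 57
  matrix_clade: Roseobacter clade
  organism: Roseobacter litoralis Och 149
  outgroup: false
  pgc_gc_percent: 59
Rcapsulatus:
  clade: Rhodobacter
  genome_gc_percent: 66
  matrix_clade: Rhodobacter
  organism: Rhodobacter capsulatus SB 1003
  outgroup: true
  pgc_gc_percent: 66
Roseovarius217:
  clade: Rhodobacterales
  genome_gc_percent: 60
  matrix_clade: Roseobacter clade
  organism: Roseovarius sp. 217
  outgroup: false
  pgc_gc_percent: 64
Rsphaeroides:
  clade: Rhodobacter
  genome_gc_percent: 69
  matrix_clade: Rhodobacter
  organism: Rhodobacter sphaeroides 2.4.1
  outgroup: true
  pgc_gc_percent: 69
SKA53:
  clade: Rhodobacterales
  genome_gc_percent: 59
  matrix_clade: Roseobacter clade
  organism: Loktanella vestfoldensis SKA53
  outgroup: false
  pgc_gc_percent: 60
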