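[PAD]
[UNK]
[CLS]
[SEP]
[MASK]
!
"
%
&
'
(
)
*
+
,
-
.
/
0
1
2
3
4
5
6
7
8
9
:
;
<
=
>
?
[
]
_
a
b
c
d
e
f
g
h
i
j
k
l
m
n
o
p
q
r
s
t
u
v
w
x
y
z
a
abundance
activated
after
alpine
amplicon
amplified
an
anaerobic
analysis
and
antibiotic
area
as
assembly
atacama
background
bacterial
baikal
basin
bee
benzylpenicillin
biofilter
biomass
bioreactor
brewery
cattle
cavity
cell
cluster
collected
communities
community
composition
compost
coral
counts
crust
dairy
dataset
dermal
described
desert
digester
diseased
distribution
diversity
dna
drinking
drought
dunes
during
each
effluent
end
extracted
extraction
fecal
fermentation
fertilizer
findings
flats
following
for
forearm
forest
fornix
from
fuel
gene
genome
genomic
geyser
granules
groundwater
gut
healthy
here
hiseq
homo
honey
hot
illumina
in
include
included
indicates
instructions
interpretation
intestinal
involved
ion
is
isolation
it
its2
july
june
kit
knowledge
known
laboratory
lake
libraries
library
limitations
located
mangrove
manufacturer
march
marine
mate
matter
may
mcra
measurements
medically
mesotrophic
metatranscriptome
metronidazole
microbial
microbiome
microbiota
mini
miseq
mucosa
mucosal
mucus
mus
musculus
namib
nasal
near
nevada
nifh
nitrogen
novaseq
observed
ocean
october
of
on
operation
oral
pacbio
pair
paired
participant
patient
pgm
pipeline
plant
platform
posterior
prepared
presents
previous
primer
probiotic
processing
profile
protocol
rainforest
read
reef
region
relative
report
revealed
ribosomal
river
rna
rrna
rumen
saliva
salt
sample
sampled
samples
sapiens
seawater
sediment
sequenced
shoreline
shotgun
showed
single
skin
sludge
soil
spin
springs
status
steps
stool
stressed
studies
study
subjects
subunit
suggest
summarize
supplementation
surface
survey
swabs
synthetic
system
taken
tank
taxa
that
the
these
this
to
torrent
total
treated
treatment
tropical
tundra
used
vaginal
vancomycin
wall
was
wastewater
water
we
were
wetland
whole
with
workflow
yellowstone
zebrafish
##!
##"
##%
##&
##'
##(
##)
##*
##+
##,
##-
##.
##/
##0
##1
##2
##3
##4
##5
##6
##7
##8
##9
##:
##;
##<
##=
##>
##?
##[
##]
##_
##a
##al
##b
##c
##d
##e
##ed
##er
##es
##f
##g
##h
##i
##ing
##j
##k
##l
##ly
##m
##n
##o
##p
##q
##r
##s
##t
##tion
##u
##v
##w
##x
##y
##z
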