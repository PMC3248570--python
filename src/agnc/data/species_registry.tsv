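epithet	code
acutus	Aacu
aeneus	Aaen
aequatorialis	Aaeq
agassizi	Aaga
agueroi	Aagu
ahli	Aahl
alayoni	Aala
alfaroi	Aalf
aliniger	Aali
allisoni	Aals
allogus	Aall
altae	Aalt
altavelensis	Aalv
altitudinalis	Aaln
alumina	Aalm
alutaceus	Aalu
alvarezdeltoroi	Aald
amplisquamosus	Aamp
anatoloros	Aana
anchicayae	Aanc
anfilioquioi	Aanf
angusticeps	Aang
anisolepis	Aani
annectens	Aann
antioquiae	Aano
antoni	Aant
apletophallus	Aapl
apollinaris	Aapo
aquaticus	Aaqu
argenteolus	Aarg
argillaceus	Aari
armouri	Aarm
auratus	Aaur
baccatus	Abac
bahorucoensis	Abah
baleatus	Abal
baracoae	Abao
barahonae	Aban
barbatus	Abab
barbouri	Abar
barkeri	Abak
bartschi	Abat
beckeri	Abec
bellipeniculus	Abel
bicaorum	Abic
bimaculatus	Abim
binotatus	Abin
biporcatus	Abip
birama	Abir
biscutiger	Abis
bitectus	Abit
blanquillanus	Abla
boettgeri	Aboe
bombiceps	Abom
bonairensis	Abon
bouvieri	Abou
breedlovei	Abrd
bremeri	Abrm
brevirostris	Abre
brunneus	Abru
calimae	Acal
campbelli	Acam
capito	Acap
caquetae	Acaq
carlostoddi	Acao
carolinensis	Acar
carpenteri	Acae
casildae	Acas
caudalis	Acau
centralis	Acen
chamaeleonides	Acha
charlesmeyeri	Ache
chloris	Achi
chlorocyanus	Achl
chocorum	Acho
christophei	Achs
chrysolepis	Achr
clivicola	Acli
cobanensis	Acob
coelestinus	Acoe
compressicauda	Acom
concolor	Acon
confusus	Acof
conspersus	Acos
cooki	Acoo
crassulus	Acra
cristatellus	Acri
cristifer	Acrs
cryptolimifrons	Acry
cumingi	Acum
cupeyalensis	Acue
cupreus	Acup
cuprinus	Acur
cuscoensis	Acuc
cusuco	Acus
cuvieri	Acuv
cyanopleurus	Acya
cybotes	Acyb
cymbops	Acym
damulus	Adam
danieli	Adan
darlingtoni	Adar
datzorum	Adat
delafuentei	Adef
deltae	Adel
desechensis	Ades
dissimilis	Adii
distichus	Adis
dolichocephalus	Adoi
dollfusianus	Adol
dominicanus	Adom
duellmani	Adue
dunni	Adun
eewi	Aeew
electrum	Aele
equestris	Aequ
ernestwilliamsi	Aern
etheridgei	Aeth
eugenegrahami	Aeug
eulaemus	Aeul
euskalerriari	Aeus
evermanni	Aeve
extremus	Aext
fairchildi	Afai
fasciatus	Afas
ferreus	Afer
festae	Afes
fitchi	Afit
forbesi	Afor
fortunensis	Afot
fowleri	Afow
fraseri	Afra
frenatus	Afre
fugitivus	Afug
fungosus	Afun
fuscoauratus	Afus
gadovi	Agad
garmani	Agar
garridoi	Agai
gemmosus	Ager
gibbiceps	Agib
gingivinus	Agin
godmani	Agod
gorgonae	Agor
gracilipes	Agrc
grahami	Agra
granuliceps	Agrn
greyi	Agre
griseus	Agri
gruuo	Agru
guafe	Aguf
guamuhaya	Agua
guazuma	Aguz
gundlachi	Agun
haetianus	Ahae
haguei	Ahag
hendersoni	Ahen
heterodermus	Ahet
heteropholidotus	Ahee
hobartsmithi	Ahob
homolechis	Ahom
huilae	Ahui
humilis	Ahum
ibague	Aiba
ibanezi	Aibn
imias	Aimi
impetigosus	Aimp
incredulus	Ainc
inderenae	Aind
inexpectata	Aine
insignis	Ains
insolitus	Aino
isolepis	Aiso
isthmicus	Aist
jacare	Ajac
johnmeyeri	Ajoh
juangundlachi	Ajua
jubar	Ajub
kemptoni	Akem
koopmani	Akoo
kreutzi	Akre
krugi	Akru
kunayalae	Akun
laevis	Alav
laeviventris	Alae
lamari	Alam
latifrons	Alat
leachi	Alea
lemniscatus	Alen
lemurinus	Alem
limifrons	Alim
lineatopus	Alie
lineatus	Alin
liogaster	Alig
lionotus	Alio
litoralis	Alit
lividus	Aliv
longiceps	Alon
longitibialis	Alog
loveridgei	Alov
loysianus	Aloy
luciae	Alua
lucius	Aluc
luteogularis	Alus
luteosignifer	Alut
lynchi	Alyn
lyra	Alyr
macilentus	Amai
macrini	Aman
macrolepis	Amal
macrophallus	Amap
maculigula	Amau
maculiventris	Amac
magnaphallus	Amag
marcanoi	Amaa
mariarum	Amar
marmoratus	Amam
marron	Amao
marsupialis	Amas
matudai	Amat
maynardi	Amay
medemi	Amed
megalopithecus	Ameg
menta	Amen
meridionalis	Amer
mestrei	Ames
microlepidotus	Amip
microtus	Amic
milleri	Amil
mirus	Amir
monensis	Amoe
monteverde	Amot
monticola	Amon
morazani	Amor
muralla	Amur
nasofrontalis	Anas
naufragus	Anau
neblininus	Anei
nebuloides	Aneu
nebulosus	Aneb
nelsoni	Anel
nicefori	Anic
nitens	Anit
noblei	Anob
notopholis	Anot
nubilis	Anub
occultus	Aocc
ocelloscapularis	Aoce
oculatus	Aocu
olssoni	Aols
omiltemanus	Aomi
onca	Aonc
opalinus	Aopa
ophiolepis	Aoph
oporinus	Aopo
orcesi	Aorc
ortoni	Aort
otongae	Aoto
pachypus	Apac
paravertebralis	Apaa
parilis	Apai
parvicirculatus	Apar
paternus	Apat
pentaprion	Apen
peraccae	Aper
petersi	Apet
philopunctatus	Aphi
phyllorhinus	Aphy
pigmaequestris	Apig
pijolense	Apij
pinchoti	Apin
placidus	Apla
poecilopus	Apoe
pogus	Apog
polylepis	Apol
polyrhachis	Apoh
poncencis	Apon
porcatus	Apor
porcus	Apoc
princeps	Apri
proboscis	Apro
propinquus	Aprp
pseudokemptoni	Apsk
pseudopachypus	Apsp
pseudotigrinus	Apse
pulchellus	Apul
pumilus	Apum
punctatus	Apun
purpurescens	Apur
purpurgularis	Apug
pygmaeus	Apyg
quadriocellifer	Aqud
quaggulus	Aqua
quercorum	Aque
reconditus	Arec
rejectus	Arej
rhombifer	Arho
richardi	Arih
ricordi	Aric
rimarum	Arim
rivalis	Ariv
roatanensis	Aroa
rodriguezi	Arod
roosevelti	Aroo
roquet	Aroq
rubribarbaris	Arua
rubribarbus	Arub
ruibali	Arul
ruizi	Arui
rupinae	Arup
sabanus	Asab
sagrei	Asag
salvini	Asal
santamartae	Asan
schiedi	Asch
schmidti	Ascm
schwartzi	Ascw
scriptus	Ascr
scypheus	Ascy
semilineatus	Asem
sericeus	Aser
serranoi	Asea
sheplani	Ashe
shrevei	Ashr
simmonsi	Asim
singularis	Asin
smallwoodi	Asml
smaragdinus	Asma
sminthus	Asmi
soinii	Asoi
solitarius	Asol
spectrum	Aspe
squamulatus	Asqu
strahmi	Asta
stratulus	Astr
subocularis	Asub
sulcifrons	Asul
tandai	Atan
taylori	Atay
terraealtae	Ater
terueli	Ateu
tetarii	Atet
tigrinus	Atig
toldo	Atod
tolimensis	Atol
townsendi	Atow
trachyderma	Atrc
transversalis	Atra
trinitatus	Atri
tropidogaster	Atro
tropidolepis	Atrl
tropidonotus	Atrp
umbrivagus	Aumb
uniformis	Auni
unilobatus	Aunl
utilensis	Auti
utowanae	Auto
valencienni	Aval
vanidicus	Avan
vanzolinii	Avaz
vaupesianus	Avau
ventrimaculatus	Aven
vermiculatus	Aver
vescus	Aves
vicarius	Avic
villai	Avil
vittigerus	Avit
wampuensis	Awam
wattsi	Awat
websteri	Aweb
wellbornae	Awel
wermuthi	Awer
whitemani	Awhi
williamsi	Awil
williamsmittermeierorum	Awim
woodi	Awoo
yoroensis	Ayor
zeus	Azeu
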