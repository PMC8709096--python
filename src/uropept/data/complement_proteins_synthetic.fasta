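>C3 synthetic stand-in sequence (1663 aa)
PKTCEWDSKWLSTCCILAKISTTHEMFFYVFWISHSSPGDHLMQHWMSHHMNCSWDHQSL
EPLMDFFMAGNCDQPPRVWSLHDMNLQMWCGTDSGWWNSNSQTIIWKTIYEDGFMGPGYL
HKLRCHKQEMSAETVDFIWEMEGRSWAISYTEFLQWMWVMLYNEHPRGEECWKFQWVSPD
ELMNPAAEDPHDVGSMECHILVMQMQPCWKGQELINREMWMLWNCDESQANTVGMIMFWQ
DKGFDSGRKHWHKREGHDRGMWMRHQNFHAEDCHAYEDKWREKWQWEHLDTGMCGMVNKK
RYKHKYLIVVTETLKCVGASIIKAGEYCQANYHGVVKQNQLRMMYLICTVKAEEENQGAW
MFDGSLKESNLLRCCYGSSKNLQNLMTGPNVAFNESFGFIWLVCPDWKTIYNMIVQCTQP
CRCQMVDWINHYCCNSHFYTHYNYRWNFKMNWSMSPFGLCQFPKVMFRMNFRENQCVLWR
NEVVLERVDFNMFTPHWMVNWAVCPMCMSNSIDEMPYKQGGHMMQFHCAWANYPTWFWTL
NMHMVPDCRNASAMIARADREPLICFIQKGIIAFSWSGFVGDQGPPQRYLRFKPQHAFMI
QKFNDAAQQNYHCLLPQDRYNWAADFQDSCLSPLYNYSFDLHKGVGYIVYHKDYKRDPPQ
LWTIKCQAHCQWYKAHFINKEPGQSFPIPHCCDPSTADGCTQWSMDLCERKGPEPFCNYS
PATSMRWMDGSETVTHSQHYVGSLPEQDEQNNVNSVWPPRLQIQMCFMINSRNSFYQVCL
TNWKKYHSAHEMWSMMAHKWLFHDDKPGLEISPKNYWIMMREFDKDYENDGGWVLSSHRF
SPFHCQPWEPHYFWFFFTSTEVDMWFGCSHCIRMLWTGGCYEIELCLEILLDVAGIVPRD
WAIFDNTAPLDKKAHEKEHHVHVRKDQVMHGWATHYQTHHESAGRVLINILQRNEGVQKE
DIPPADLSDQVPDTESETRILLQGTPVAQMTEDAVDAERLKHLTQHLCSMMMHPYPFPPL
RVCCCRCLMIPHRFWHYVNYSFWAQAEVNCIDGCMIQPAWGNPSIEVCEAGINLFCSLHR
LHQHEKRHYRVVDIEYMRCMCMEEVCTWNGMDRIHCDHRDLWVSIGTSCIGGLRNNNEKD
MALTEWRHGVEIDFIWQEPPNFCDREIKHMTFYTMQQNMMNQCCWEPRITFQAIGKVQGN
ITMFVGDSRYLTTAKDKNRWEDPGKQLYNVEATSYAWMCVSKWKHCNACVWIAQQFMHET
TVGEMHTSKKYKVGMQQALAQYQKDAPDHQELNLDVSCMYVPIGKFQDLHEGWRICAQCS
MCREVATEFRDYSYLDHRKNCITNQCCNEYIRYMNSEPSQGLLDPLARCIWATYDNQGWK
SRWPCLFEPECPSGQWEKDYAMHMFFRIPCCHFPFTDCQCIGTHEDVYIGTDENMHMWLP
DVQKCAQWKSQGQIYIGWCENGMYDKKDPKMKQSTGVFTGFPTSVWGHWADIFAGQVPTR
LMCEVWESPLQYNFNWPGGKGKMCWRSLRESERNKAILRHYCWYHQMRWIGVISARYYSG
QQNKWNSLWVPPCGQWDLIQRDNLTIQQVYGSQWYQKKYTIKPKFPFSMCRGPWRAEFSV
PIWVRNLDPNGRESTWPRGIECCFRIGRMISEESFHAEDNRHR
>C4A synthetic stand-in sequence (1744 aa)
LSYVHHHSKEKAHAQGPIINNTHDVMGGYHKWDIQQGLNFYMESQGLGKANSYSQYNTKE
CMRSPRSTGSLEDFTEDLAQHNKGSISHMHHIRSIMGEEGHIIAPLWAHAISRNVDRAHS
GAGCQVIGDYFEAKPYCGAGGEWPMTGHFDPIHEPFFMKCFDRGRDYGSESLFIWARLEQ
DHFKQMNDQCMWRMEVNGASFITYILLQCKRWNVMLKAMTTPYYCRIKFQTEWFVFEVFQ
TCMKVCTLTPIQKQQIARDTIAFLSCEIKYPCHPGFLMRFKRISIMWDQAPVIYRYCNYS
PVARTMYVSSDMRLCKYMSEGIHRGHWTAILSIRNNDIHTPTTMIRPETLTPDQRPDRNK
PLYRYMWGYPFELSLHLDNDIKGCYTLVVEPNPLRIVQNYQVEHVGKDQHSWEYNYGRCP
RYIHNVRSYHIDDHVIMVCGSGLDGQPIYNCITCAFTANGCPHAKGVCIQRIYENKGTKM
DGNVCVEGECPTNAKNLAIDIIKAACDTTHLGHHYQPDRDFDWVYMDDNDDNFIMAVKET
YIEASRMKVKDPKGRHHMPVYDIWLNIASNAIWWKCLAFWHLHILMVMAHFDVPHCRDQN
VKHENGTCICIWYNYRSKNEGRLTDDVACNTMNVIKQQEPNPVIQFRTRDELSGCCQPMW
PYMRGAVELMCNCGLYFCCNKEWAANEMMDVQPGSTDDDQTVSAVRWENFNMNSFDWFSG
RRWWENVSAQMGSDHDCDRHGKFNQFKNMSHPRTRSGSYDMRDTIYQWDRTRTCQDEYRL
HWHREYHIPSLWHYGKAIVICFMISDQYYPYRWEGCAMVKLQYDTQLIMKGGHSWWEPVI
AIDMGVKWKGYQVHDHNDSHGEYWVKGQTIIEGCDELMQSEPGMLIHRIWPYEDMQKRDN
IHCTSQVFQTQMCEQKLVWWGPLFLRFESFTEAPQQKGDAIYYWRTGMIWQKGAKQNELC
TDSICFRQWYVIFWFNAWPKHPKSMIGQTHNIYPNFRINEFGPQPCCFNHWMRAFADLFG
VWDFTKWVHTWMTSTQKTDGQRVNWWIYIGADGLDLVHWNLNWEHLDIMVTTVHWTFNIH
SCTQHSSAQWTYLMHNPEDAFLNTVRTWGLVTANMAGRNGHTDEYIGDTYVRYPYKAHFD
NTPLTIGDVPAEDPCCKWVPIAICNGKDEPMCWQMKGDKVSYPYSPFCWRRMEEEYRICI
TLTKAPVDLLGVAHNNLLHCNSQYQFQDISYWCRIRPNAPLGWNDDMTQGTIFQFKHTWP
KAYITPDDAYACDIFTVWDAPQMKHSYNNADAGQDHGQYEPFTTLCGWRYEGPKPGMTRW
RWYFKRGRSFIFTPSDTLQVITMFDDWSPYHAGQMPVERTRDLLLIDFFWFPWKNRENPN
ESLNNDFCERPMVMFDLCFDTRHYSMKRNRTISYVCERLSESPVHFHRGKREAIYSCRLV
YYYKCHVFTYHGCHDYCRNGLFSLPVRSELCAVEHREFKGYFGLGQKNWGRGETKNWCWI
EQNSKMNSHHFHMQQRFQNMGNSMFVTACWHKHQPGHCAEQERSFDAAVHDPKKTCAITI
FWLGDHDTYFFEFWFKYSSVVMLVQHWNLFSKQGDDFFSEVHYCESIYDIKKSFRFKFAA
QSMYRPLSNYQTPYPLKSKYDYLEGWFHDNYHWSWKNDKECQNFDVFIFNRVECGSRVML
AMQPFADTGFNSQFWDYKKPLPHHQPLYQAFMNNVTGENYYRDSYLGDDLYVLLAWRCNP
HQES
>C4B synthetic stand-in sequence (1744 aa)
PMIYGDGMLAHPLHMMIRFQNRNTPQWEMWIGLNAMTSSSMEDHRKCTFTQRPLHSNDWK
TYDIKKVLSQEHYEWRLLQVHIMPNFYMARCQWIMMCQFYNFARSHFHNLKPMQKCQGGM
LATAMDPVHCRPWFHTHRAFLHQQLCALVPIWWVWDPGIVNTANCEIESGIPCTWESMST
FTIHESKWRGPFPSSRVKWPWNPTGKLKDVEYLICETREEQRSMWSLNLWPCGYEDPNPT
LSPSQECASNVDQEHPPGFWILSKALIMCRWQLHMWVYKPAWCPRSHGELEGIQCMDEQQ
YVMCNRYQFRGQFEIHIQGPWSIYPQDMTCYARFGNSEGPVFSRKETTCAIMDPVFKPAA
GRSAGAHGVRNMTEDDTYTGVMHPTGVQTFWFLLVTFPASNGHQFKDGWCPRGFRSVKFD
MDVYQAKMGLWAAAFINCSCNIFNSFPTPRPGQTVLWEHHKWPEWSMYWMEPHKGQSFWS
WNDKSMPQWATCTMTYMAGMNDVVFVGEYKMHLARLAQSKPETFHECYPAPGFDTRKWGH
SEFCMDNVHHWNTNSWTMMKHLAHIMPHNCEYVFPMRQFGKMYPPDCYWWWGFKASWRDE
IPYMTMLEYWVKNWILNFQAYHRHGQKGCECYTNFCQNMQVPQQMQTNGAAHKTDQHSQY
NGFTMWSSTACTEDVGARMNINVMNRMIALHWVQSEGIYFGLVDWLPHCPCRALFNGVHL
QPVLIPCKYHVKYKGFSWQQFRTCCAHRNKPASMCPHYQRRTPSTMGELCKCAGCAVDYQ
WSTVLPMMHAEEPRLEIWVQKAFPYQTGKMNTAGSCQVAKPEAVYFDLIMLFKSEQPDWA
ELLKQPCRVDDWFEHSHTMRNRQESLMVRYMFTVIMNYSWLEPTQIAKTCVKVKDRPYLM
PELCWWHDVEQHPTTVGRYHQKPMFGFIARTFGSAKRHMQPWDTYKFTPCVDTGCNAWMN
VDNAKHGDLTNMFKNNQCPYFKQPVANWYPKYGGMEPPEPKECICWRMAPWDTCWYTCKA
TSGCLNAMDPKIPNPMMIEIYRIRRCLNYWIQDKDSNLTEHYGVMCVQVKHNAHMPHWWY
VYWVFFECQTEPPKCVPFGMHKRPYIMEFRTRCTQQFNCARGKVGNWWWFPFMLHCHKYE
MNADMPMFVFNYWVKNWIVCVIMDSMWTPSEDMHTCTHPWHNEFLFASTPMTALWDGCLM
TLTKAPADLRGVAHNNLIYIGDLYHNNPRSCPGVQHNHKSRGQKICPMARSPTTLKSMRF
YYLEEWSCMCLDAQHTQYPDKPFHRVHRGGHMAGMASPDEGNSIFEYSLWYALAFRGFIP
MCWNDMLVCEIEENFDKNENKQWHRCAKPEQPREHFYVNGDNEWEISTLYDIANDWFGHQ
PECGMMVHWLTVVCGVRPQTGGIYLLPIPGYLSQLVAPYTSSDELPAKDDPDAPLQPVTP
GPSQQDFGHNEHVIPAYFYLWIKNCACQHSSHFWLCLDTTHKCPKGNNGPAPFFKKAAGK
INLNLEKPYPNDMRLTNELANIIKDRLSYPVPLAKICVYNLGFIGYFYQHPAVWEKWWGS
FAEWFITFLGYDNRWANECVTVGGHKASRYRDVCCHSADWDIGLAHSAPWTDRFTLCDPV
LTLNAPRDVSPLTQYEEIEFRYQMLDQWMAWSNHQNQNDDIKNLTSPHAWRMHWRSTVQH
HPMNMFEFLTYCYMHTHRLVESIKHIFVINVRGHKTANYENPFRQTLWYEPKYMCEPKAC
QGKS
>CFB synthetic stand-in sequence (764 aa)
EFYDVVSSKCACGYSELITGKFMTEYNMASWCPMGDYFYWKNAHVMRFNIGPGHGSQEVF
TCINPKVIMCYVCAPQAHPIQFTPSIQTMPSCSFARVEWTAEPRKRAWTPPEEFNYSTYI
GNGGMWDMFPTWDERCDMDHSQKSERMRWNEYATMWCRSKCFKMQICHMIMMVPTLGVLI
CSPLWKCQHCMSIVLTFGKPPQHTACVGYSVNREPQCGQHMKCYFCGEHSVFKFLSSLTE
TIEGVDAEDGHGPGEQQTGHVFHGVRDWSESFREQPVAKGDWQEQQVRNAAYMVWHCHTC
YVVQCVIRKGILANILPSCKYGIDWTGMPISHNETNSMNGCTIEKWKFYWIGVHDIGGDP
QRCTCRTTYRSIHLVDYATNFIQLAYMYLIAEDKVHAYSFQKDIVISGVDGETHNFMMSN
SHMQWHWGQRQVMFVNTWPRKAETTNMTQNGIHFSIFACQMQFIWCALNAIRCTYVDAAK
LKIHPIKACSEEDRWVDFPMMPPDRPADVEAVTMGAIDCVLESRMVILRFMRQGQMSLRS
NKEIRRMQFKKSNDQEYYWGMIIVQDKWCAHLFFVYYVQHYNNEACLQFTYFHKVYRTAC
TDTQPPHACMSQVCEIRILWVNVADKTIRWSWMMNMRGPLMSSVEEHIRATWLDEQSRKD
NIEYQSHYYCCIYAPMFYIIDNMCFHKMHKCLRAWKTSKVVFFMVKDCLSILYCGQLVTR
GCDYMAISHQDRGMYYGLLMTRWKKRHDMVRLSIDCMIVQLEQF
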