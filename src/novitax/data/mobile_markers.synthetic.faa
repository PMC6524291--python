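>phage_capsid_1 role=phage marker=capsid synthetic placeholder exemplar
KQLGTAYKDMHWDTGFYKYYCLAEAAQWTEAKRGTNTVSYRCVHSHCRVPANSRPAQCMVRDHRPAPDDDDAPMRARKVN
RWSGYTEYGHEPVMHLIRGKLEITECTMQFSGTKYKKVVHAGTSPMGGAHTLTAEKFAGNQLLFCEVWAHTSVATNASEK
EAPFRTVCTKRPLVHNWAQEIHQRWNEGVANQKIRFNPWQHMNYSWEHSLMEIVITPGEHLGPKYTRVTGCWVCKINALT
CALTPSMPNTHQWHHWCSCACQPEDSRQTGYDPQELTVMYL
>phage_capsid_2 role=phage marker=capsid synthetic placeholder exemplar
RQLGTAYKDMHWDKGFYKSYCLAQAAGWTEAKRGTNTVSYRCIHSHCRVPANSRPAMCMVNDHRPAPDDDWAPMRARRVN
RDSDYTEYGHEPVMHLIRGKLEITECTEQFSGTKYKKVVHAGTSPMGGAHTLTAEKFAGNQLSFCEVWAHTSVATPASEK
EAPFRTVCTKRPLVYNWAQEIHQRLHEGVANQKIRFKLEQHMNYSWEHSLMEIVITPGENLGPKYTRVTGCDVCHINALT
CALTPSMWNTTQWHHWCFLADQPEDSRQTGYDPQEGTVMYL
>phage_terminase_1 role=phage marker=terminase synthetic placeholder exemplar
VMMPGFQFTFMALPMIIYNIRPGWWYGTYFFGSYCIKAQTFRVGMQVHTLSGFHKESVHSTNFHQCSSSTRTSFCHIQHI
ISWLLWHPNGHIMVWESQKWGYKCSNIFCNIMEFGAHMCGWALGTKAMPTLATFDDNWQSAQDVTLQATDSSQLSVKTPI
EWINMHYKEAHYFWDLGMEILWAKMITIKYDPITANCQFCVRSPSMPPIDCLRWCREFMLDKPEYEFKKTPPQDKLAPMT
ALNAEKHRIKGWPMQKFKEMQWMEYYEGCWEMNKADQPASEDRASKATSKAHGPFQTGRNMEHGDKPRCIYLQASASRLE
LPMNDPAMQHTIWTEMMWINSPPIVSRVDYLCPPNVTQKYIHASWECLGSWPEPLGLSG
>phage_terminase_2 role=phage marker=terminase synthetic placeholder exemplar
TMMPGFQFTLMALPMIIYNIRPGWPAGTHFFGSYAIKALTFRVGMQVTWLSGFWKESVHSTNFHQCSSSFRTSFCHIQHI
ISWLLWHPNGHIMVWELQKWGYKCSNIFWNIMEFGEHMCGWALGTKAEPTLDTFDDNWDSAQDVTLQATDSSQLSVKTPI
EWIHMHYKEAHYFWSLGMEILWAIMITWKYDPITASCQFCVRSPSMPPIDCLRWCREFMLHKPEGECKKTPTQCKLAPMT
ALNAEKHRIKLGPMQKGKHMQWMEYYEGCHEMVKADLPASEDRASKAYSKAHGPFQTGRNAPHGDKPRCIYLQASASRLG
LPMNDAAMQHMIWTEMMWINSPPIVSRVDYLCPPNVTQDYIHASWECLGSWPEPLKLSG
>phage_integrase_1 role=phage marker=integrase synthetic placeholder exemplar
EPHHWGQAAMPSEFLRLDWRGRPYNYVYMHKCDNVDDALTRNNDARKGHKKRENIIGDIWNSRSGEMYVQYYHYMWVHVH
KWGSFWQCPDQFQWYFLYSTRRLLYTAWEVGTAVFWTKEMLDCMSSDIFQCPIWLWMPWSIVWMFKPMFFSFPGQHFKFE
RKIEGYTDDIRSWKEMMTVDSILSEFMWWKIVTRHGLRVDPKPVGPAAWVNYGFRRNYKHQMMNSDQTKLPWNGCSYIIP
NGSQDNWHHMSSPEHNKIYCNVNAASCVNCPSVVGIDNEMSQTNAWCRVGIDDYTPAAAWPATNSHLTGSNKCQQES
>phage_integrase_2 role=phage marker=integrase synthetic placeholder exemplar
EPNHAGQAAMPKEFLKLDWRGRAYNYVYMHKCDNVDDALTRNNDARKGHKKREIIIGDIWNSRSGEMYVQYYHYMWVHVH
KWGSFPQCPDQFQWYFLYSTRRLLYTAWEVGTATFWTPEMLDCMSSDIFQCPIWLWMGWSIVWMFKPMFFSFPGQHFKFE
RKIEGYTDDARSWYEMMTVDSILSEFMWWKIVTRHGLRVWPKHVGPAAWVNYGFRRNYKHQMMNSDQTKLPWNSCSYIIP
NGSQDNWHHMSSPEHNKIYCNVNAASCVNCPSVMGIDNEMGHTNAWCRVGIDDYAPACAWPSTNSHLTGSNKCQQES
>plasmid_relaxase_1 role=plasmid marker=relaxase synthetic placeholder exemplar
QEDYIYPREQLNYWWENTTVDDSYIWSWNRPNHEMLQPGFSKIIQFYGLQSRSDTSNWRCNARQYIRVRCNSCAFAGWQQ
CHAYVGAEYICVFRNTLAAEPLMGERPAFECESMWHHETVFTHTFWLALYMTYPQNPNMKIIRQWCDGELPKTIGHHKAV
VMWKGMDYGRFLQTGSWVTIHWIEWSMPFMDGQDMYTPLPHCHLQFCYYKFWTKVSARCSQKETVCLWACIDIHGIIHQF
NAEIEMGTQGWGKKAGSHENIRMDEYISDAFDMCVGNRQHTRFWIWNDNPVQPVTKIGLVIVACQEQSRLGNVALQ
>plasmid_relaxase_2 role=plasmid marker=relaxase synthetic placeholder exemplar
DEDYICPREQLNYWWENTCVDDSYIWSWNRPVHEMLQPGFSKIIQFYGLQSRSDTVNWRPNARQYIGCRCNSCAFAMWQQ
CHAYVGAEYICVFRNTLQAEPLMGEMPAFECEYMWHHETVFRHTFWLALYMTYPQNPNMKHIRQWRDGELPKTGGHHKAV
QMWKGMDSGRFLQTGSWVTIHWIEWSMPFMDGQDMYTPLPHCHLQFCYYKFSLKVTARCSQKETVCLWACIDIHGIIHQF
NAEINMGTNGWGKKAGSHENIRMDEYISDAFDMCVGNRQHTRFWIWNDGPVQPPTKIGLVIVACQEQSRLGVVALQ
>plasmid_mobilization_1 role=plasmid marker=mobilization synthetic placeholder exemplar
LYSPLYCCIVVQLATRVWLQQIIMVYLTIAKPAIYCDPAHKVNEVGNINGEQDQMFRDAKVNVIALIKEHIKFRGCEFCA
PFYRAVFKYSKRYHRLLLWHWRGTQKSKACSLQSPHDTHDCEYSWDWSCIRVPNEAHMTFVQQYNFDPMEMQARAWGDRH
QTMDRMLPPHYGHENVSMAGMHSGKQCFDAMQGNFAWSLSLNYMIGNQVRDHQGFRWQSYLCMLLHKLTTQSACKRCFYL
FFDETICIVDLFMCHMSGECRMAIAPNFKIVTPAVELRCDQEQCCLPEDWYSCPWCALSLPKSRMAQNAVQEAPMCQLCD
RYNWMVVCTLAMFEKMQNHIQESYVMIQDFFRIIILF
>plasmid_mobilization_2 role=plasmid marker=mobilization synthetic placeholder exemplar
LYQPLYCCIVIQLATRVMVQQIIMVYLTIAKPAIYCDPAHSVNEVKNIHNCGDQMFRDAKVNVIALIKEHIKFRGREFCA
PFYRAVFRYSKRYHRLLLWHHRGQQKSKACSLQSPHKTHDCEYSWDWSCIRVFNEAFMTFVQQYNFDPMEMQARAWGDVH
QTMDITLPPHYGHENVPMANMHSGKQCCDAMQGYFAWSLSLNYMIGNQVRDHQWFPEQSYLCMLLHKLTTQSADKREFYL
FFDETISIVDLFMCHMSGECRMAIAPSFKIVTNAVELRCDREQCCLPEDWYSCPWCALSLCKYRKAQNAVQEATMSELCD
RYNWMVVCTLAMFNKMQNHIQESYVMIQDFVRIEILF
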