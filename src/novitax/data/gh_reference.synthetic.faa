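>GH3_beta_xylosidase_1 family=GH3 subfamily=beta-xylosidase synthetic placeholder exemplar
RHHCAYWAALYKPFHRWRCRYAYSPTFDNNMETAVSWRCPYPCFKRQYWDGCREAVHMGEQCMLHHQFIVQVFQVMLYTM
ILGHNIQIMKMENPAKGIQWIGCPVEQAHRWIPASWMVGRDIMPGSAKVSNDLWAHQSHVYNYPQIFAYIWNHNSKMGCI
HMFLMLPIHLTKDHVNLDGQRTAPTASASNSAQKDWEQCDEMVLCPWPPPYMHARRRGDYDLMEDTYETAYMLFEFHEDP
WCTSMKDTQTKRPNCKQQPHLEDCCKRMGECDETSTSVCQHVHFGTPEPGHCEPAEKSYGKRQQVDLGDCSFLMFQFQFW
YIMSIAPAYPNLWPGTIQTNLGVWWRPWLTYAMLLNVCTIPIKHY
>GH3_beta_xylosidase_2 family=GH3 subfamily=beta-xylosidase synthetic placeholder exemplar
RHHCKYWAALYKPFHRWRCRYAYSPTFDNNMEMAVSWVCPYPCFYRQYWDHCREAVHMGEQCMLHHQFIVQVFQVMLYGM
ILGRNIQIMKMENPAKGIQWDGCPVLQAHRWIPASWMVGRDIMPGSAKVENVLWAHQSHVYNYPQIFAYIWNHMCKMGCI
HFFNMLPIHLTKDKVNLDGQRTAATASAINSAQGDWEQCDEMVLCPWPPPYMHARRRGDYDLMEDTYETAYMLFEFHEDP
WCTSGYDTQKKRPNCKQQPHLEDHCSRMGECDETSTSVCQHVHEGTPEPGHCDPAEKSYGKRQQVDLGNCSFLMFQFQFW
YIMSIAPAYPNLWPGTIQTNLNVWYRPWLTYAMLRNCCSIPIKHY
>GH10_xylanase_1 family=GH10 subfamily=xylanase synthetic placeholder exemplar
CWEAKHHDSTVEKQVYVAQVLRLHPCENTEPCVNHGGGDKKQSEIITMRHAGQTCDVNMMNSDGRIQQWIHRCKSPISKP
FYNKVFDLQDHNCRGAECCCGMGGDIRAMQLWKKLIVSRHVLILIQAKVCFEAIWQCLVRHTVSSPRLIWWCNAEQSWWS
FEGWKLDSNPYHEIRVCCYAGPLDQRLKVILEAHRNAYQMIGGLNETSTIVKFACWRVRHPKCIKKTNSQSVLLCNKLDC
TALQKGMPCTYMMEGFTCIPSMSGAPPCMRENYMTKNASNYSYYGQCFWNDNHKWYKNCKEIGSLYRDKADFFVEEGSEF
YLWSKHAPEYVSYHHFKYHREDWLRLQDFKS
>GH10_xylanase_2 family=GH10 subfamily=xylanase synthetic placeholder exemplar
CWEAKHHDSTVEKQVYVAQVLRLHPCENTEDCVNHGGGDKKQSEIITMRHAGQTCDVHMMNSDKRIYQWIHRCMSPISKP
FYNKVFDLQDHNTRGAECCDGGGYDIRAMQLWKKLIVSRHVLILIQQKVCFEAIWQCLVRHTVSSPRDIWWKLAEQSWWS
FEEWKLDSNPYHEIRVCCYAGPLYSRLKVILEAHRNAYQQIGGLNETSTIVKFACWRVRHPKCIKKTNSQSVLTCNKLDC
TALQKGMPCTMMMEGFTCIPSMSGAPPCMRENYMTKNASNYSYYGQCFWNDNHKWYKNCKEIGSLYRDKADFSVEEGSEF
YLWSTHAPEYVEYHHFKYHREDWLRLQDFKS
>GH11_xylanase_1 family=GH11 subfamily=xylanase synthetic placeholder exemplar
MHIAEPGHGRMEQNCQWRCLVHKNTDVKQSWTVVNIIYWNTMPFYNGHCKMNKLYMAQMIMNGMRLDMIYWMNGAKLERC
QPRMDIFCGHRVFAFSLCCSTYGNVDKLEYQSIIKLFKTCLFTKPLCKQHLPADIASWANVWSEEWYGYPMEVNSFYCRW
KSGCPRLKQGRVLPYVGCYYVGWREIGKSKECPAEDHWIMLAPSETFLMTPGPCCMETDSFYLFKQFPTMWKCWRVQRNW
EQQDPCFYKQVMIIHPEHIGYHIRIIYMTANPIGSFYTFNWYNHLSWPHHVMQEMQKLGMSYKIQLLKL
>GH11_xylanase_2 family=GH11 subfamily=xylanase synthetic placeholder exemplar
MHIAEPWHGRMTQNCQWRCLVHKNTDVKQSWTVVNIIYWNTMPFYNGHCKMNKLYMAQMIMNGMRLDMIYWMNGAKLCRC
QCRMSIFCGRRVFAFSLCCNTYWNVDKLEYQSIIKLFKTCLFTKPLCSQHLPADIASWANVWSEEWYGYPMEVNSFYWRW
YSGCPRLKQTRVLPYVGCYYVGWREIGASKECPAEDHWHPLAPSETFNMLPHPCCMETDSFYLFKQFPTMWKCWRVQRNW
ELPDPCFYKQVMIIHPEHIKYHQRIIYMTCTPIGSFYTFNWYNHLSWPHHVIVEMQKLGNSYKIQLLKC
>GH13_pullulanase_1 family=GH13 subfamily=pullulanase synthetic placeholder exemplar
LLYMFIEFKRHQNNMDQLIHEHTKTSLLLSWNCDCLYCKTYTRPKESRDCNVFVVLMDLTWHRVKEYRWPIIRPMKVFNY
DLHKNIARYLDMSTRRQKTNFGTVRHDCQDQMGWEEQTHEAPWTQQKKPIMSSYMHLAHQDPHMFYRFTTFWPVVVAWIA
KVLDPAGKMIFVDGKIGMWNLRPITVMRAHVTSRLSCKIPWPKSMCRHDCMLRGCRMCFQDRIEVTHDYMIVYDHFCDQI
VWHSIAVKIGSNDDLMFIGKDWTLSPHTTSVAFDDVLHDSLAQQGPIWTLKLHDFSQNVFCAWKNMERCYMMIGEITLLE
AGKVAATEWLVQKSFQMNSDILSLRICWYRWCQYYEETPFN
>GH13_pullulanase_2 family=GH13 subfamily=pullulanase synthetic placeholder exemplar
LLYMFIEFKRHQNNMDELIHEWTKTSLALSWNCDCLQCKTYTRPKESRQCDVFVVLMDLTWHRVKEYWWRIIWPMKVFNY
DLHKRIARYLDLSTRRQKTVFGTVRTLHQDQMGWEEQTHEAPWTQQKKPIMSSYMHLAHQDPGLFYRFTTFWPVVVAWIA
WVLDPAGKMINVDVKIGMWNLRPITVMRAHVTSRLSCKIPWPYSMCRHDCMLRGFRHCFLDRIEVTHSYMICYDHFCDQI
VRHSIAVVIGSNDDDMFIGVDWTLSPHTTSVAFDDVLHDSLAQILPHWTLKLHDFSQNVFFNLKVMERCYMMIGNITLLE
ANKVAQTEWLVQKSFQMNSDIHMLRICWYRWCQYYEETPFN
>GH13_amylase_1 family=GH13 subfamily=amylase synthetic placeholder exemplar
NHHDRWWNSQLVGCMWCTDFHCDYFADEQLGANDVVMVTLFDMNRHFLSDGHIAICPDMFLTCNNMMLPLHSCLILRMHL
QKFMIHQGIWIPMINKARMCNHWKKAEHSTSPTWLYHAVEILSSDGCAAYWIRAMHFQWGVQACCCMCMLPCKLGPADHF
NVHQVGPWKNPCASDREQTAGPFVVFMCHSAMGMHMIKWIGDAKFGDGWAITRAGCLQAQPMKLGLEQKYCGFGGSYVAP
QMGLDGCFWSHYMTTRVFVPGKMMLVLYLPYGYSRWVGRYDPWPLGCWKLITHNGNCSLYFWVDQE
>GH13_amylase_2 family=GH13 subfamily=amylase synthetic placeholder exemplar
SHHDRWYNSQLVGCMWCTDFHCDYFADEQLGANDVIMVTLFDMNRRFLSDGHIAICPDMRLTCNNMSLPLHVCLILRMHL
QKFMIHQPLWIPMINKARMCAHWKKAEHSLSPTWLYHAVEILSSDGCATYWIRAMHFDWGVQACCCMCMNPCKLGPADHF
NVHRVGPWKFPCASDREQTAGAFVVFMCHSARGMHTAKWIGDAKFGDGWAVTRSGCLQAQPMKLGLLQKYCGFGGSYVAP
QMGLDGCFWSTYMTTRVFVPGKMMLVLYLEYGYSRWVGRYDPWPLGQWKLITHRGNCSLYFWVDQE
>GH43_beta_xylosidase_1 family=GH43 subfamily=beta-xylosidase synthetic placeholder exemplar
LGSTIMWDSVACEEFKDIVMFFFIPWHWRYPPQTGTNRKPSEKQSYTDIMEWNPYTRQQPSWDKYDPSGMDLRRCWDCCK
TSVKCIDTMGGTNFPSHEQECYPANGNPVWTWGPDQGHLDFTDDGIQQYYKQPQECLFWGGYAHNGHYNSYCGKIMDPNG
YAIWFSSMKNAPCMACQESCEYKTYDTVGCPWRCVDGSPAYIITSWLPSNPMHCMNKDGNYHPFIHVAHCQRHDQNKMYR
DELAVSKTIIQDRNDVWEADIFLTSNSASSTSIHWIRHDYWDIEKNIVDTIPGMMYMYIREVTDCCDAF
>GH43_beta_xylosidase_2 family=GH43 subfamily=beta-xylosidase synthetic placeholder exemplar
LGSTIMWDSVACEEFKDIVMFFMIPWHWRYPPQTGTNRKPSEKQSYTDIMEWNPYTRQQPSWLDYDPAGMDLVRCWDCCK
TAVKCIDTMGGTNFPTHRQECYPANGNPEWTWGPNYGHLDFTDDGIQQYYKQPQECLFWGGYAENGHYNSYCGKIMDPNG
YAIIFHSMKNRPCMACQESCEYKTYDTVGCPMRCVDGSPAYIITSWLPSNPMACMNKDPNYHPFIHVAHCQRHDQNYMYP
DELAVSKTIIQDRNDVWTGDWFLTSNSASSHSIHWICHDYWDIEKNIVDTIPGWMYMYIREVTDCCDAV
>GH53_arabinogalactanase_1 family=GH53 subfamily=arabinogalactanase synthetic placeholder exemplar
MDTSTYFHFFMCVNQLVEQFSWEWSTVCDNLKLTQRYAKPGWIQMIMQPLYRLNKFMIHFSCGMRQTNSRCYQDEEDLFW
HLGQRIGPMKRKNSNVRHVEQAFTGKFRQERPPICCERCTWQGMNDNIYHSLNHYDLCCCMKHVHRWQFWDGMSDNLCLA
WLYSIWRPMSTHHARLTFKRNGNLTLSRDGGSLLCMWLFRNSDAQEPHLQNPEFSTPYVMQQDAHDKIQHFSCSPSYAEP
VVVHWYHATHWGMLWGARHSKCTKSDKSYLLHYAIDEECEMGNWYDYKWSYACFHLWTKCAHGYKWQAFIVYAPLGTCIM
CIY
>GH53_arabinogalactanase_2 family=GH53 subfamily=arabinogalactanase synthetic placeholder exemplar
MDTSTYPHFFMQVNQLGEQPSWGWSTVCDQLNQTFGYAKPGWIQMIMQPLYRLNKFMIHFSCGMRQTNSRCYQDEEDLFW
HLGCRIGPMKRKNSNVIHVEQAFIGKFRQERHAICCERCTWQVMNDNDRHHLNHYDLCCCMKHVRRWQYSDGMSDNLCLA
WLYSIWRPMSTHHAMLTFKRNQNLTLSRDGGSLLCMWLFRNSDAQEPHLQNPMFSAPYVMQYDAHDKIHHFSCSPSYAEP
VVVHNYHATHWGMLWGARHSKCTKSTKSYLSHYAIDEECEMGNWYDYKWSWACFGLWTKCAHGYKWQAFIVYAPWGTCIM
CIY
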