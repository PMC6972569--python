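>MCM_ref1 class=MCM synthetic
FWGIEEYETNLVPLRFIPNAFYMCIWSQQHWHFELFFHKIHRSVTGWYICGCNKYMYVVA
RCVDHPMDWFDCPEQQIVQWCCGRNHQIKCTYVCWWAPENGDQGVQVENRLMWCWTRELR
VPIERDFNTWGRQKVYMTGEDTLRLRIAHDTSWKQDETSGVDDRAHFWYFGAHREQWRHK
ILCVKRQEDCFSYGCIWKLDSISVWTEMKCGWRLEPHSWVMIETEYAECTLYVVDCVCPM
FAPEGIILECDFWSEAITLVFETKATESLYYCQFRIWGAGVTASWCNAKFCKMWCVGLAW
KDIWRIVTIQVKYACCSMFEYIKFLTNKYPFLIVATIYSCLPLSHNAPAVAHQTKYKSDR
AFYIEALAHDMVDGWKHAEFGCRKSGGGRCNEQDDSIDWDATKQGWSRVHLDAHWERVFP
>MCM_ref2 class=MCM synthetic
FWGIEEYETRIVPLRFVPNIFYMCIQEQQHWYFELFFHKIHRSVTTWYICGANKEMYVVR
RCVDEDMDWWDCPEQQSVQWCCGRNSDNQPTYVCWWAPTNMDQGVHVENRLMWCWTTELR
AIDERDSNTWGRFWVYMTGLDTLRRRIKHDDFWQQDEEVGVDDVAHQLYFGPHRNQWRQK
IYCVHRQEDHFSLGCIWKLDSISVWTHMKKGWRCNPHSWVCIETNYAECTHYVVDCKHPM
FAPGGEIQECFHCSEAICLIFEEKATESLYNCQFRNWGAGVTASACNAKFCPYWCVHCAC
KDVWRLVHIQVTFACCWMFEYLKFITNKNPFLIVANIYSCLPCSHIAPQVAHQTKYKSDR
ALYIEWRAHDMVAGWTHANFGFSKSGVGRCNGWNDSIDWDATHCGFSRVH
>MCMlike_ref1 class=MCM-like synthetic
AIYSHFKCATGVKEQYKVYNNEFGSKLMADQCIDFWKLNMWLGHHTVDHWTNHCDNGIQN
YILVWGQDFHKIYMLTPPIISFYQDHCIHLIDMIHTSTYEMMDMHAMWFSKWLEHPIQME
IKCAFVYYLSTRVIGGSWLWVANLLPAFSYKAMIHIEIENYCPELHMEKQCPHAIGKTGK
DCTQMYYIGGTVVPEEHQCVNYKLIDEGNFSPPALDYSYFAEPNVPTWGCFSQPVTCVDT
GTQMNCFRPRMDHCSYTDRGAMFRPMYAPIAGAPEDWGKCKDIHVGPFTRVMAVYREQTT
GMDIMYFPHAEEGIMDMARQPRSKNRWYAKIFYIPASCHWCFYYICYTMDFNQCIVTLGK
GRPRIFNISMFGRHWQEYKW
>MCMlike_ref2 class=MCM-like synthetic
RIYSHFKCATGVLEQYKVYNNEFQSKLRWYQWIFFDKVNMFCGHHTWDHWTKHCKNGIQN
YTLVWGQDFHCIFARTFPIIYFYQDFCISLIDMIHMSTYEMMHMHADWFSKWQEHPINAE
IKCAFVYTRSTTVIGYFWLVVANLLVAKSYKAMIHIDIENYCPELNMEKQCKHLIGKTGK
DCWQMHYIGGDVVPEEHQCSNYKLIDEGNFSPPALDYWYMALINVPLWICFVQPVTCVDT
GTFMECFEPTMDHMSYQDRGAMFRPMYAKSAGAPEDWEDIDDIHVPPYARPMAVYAEQKT
GMDIMYFPHAREGAMRMGRVPKSKNRRYAKHFYIKDSLHWCFPPICYTMYFNQCIYTLGK
GRPRINNISHFGRRW
>t26_22p_ref1 class=t26-22p-like synthetic
LTEHTFSAIIECQYPKNMRDAWICSYFDMWDRMQVACMIKSTKVINRLKDRMCPHNMMRG
MHMQSYNASILAYKGLGITQNQQGKCYPFQKLTMNVAYHVFQLTLKIICFGKAAKCWHLL
EYYCSYAHVKIVNFYPNQYQMNHRFTDDPDILTNWYFVSYFTLYTYLSRILSHGPAHQLD
QRCTKGRVHQNQHHGGEQMALKEYFYKAKQWIMWPNMVNHWSYAHHLEKHINLVDMAMPM
KTWYRAITDIAAGTFNSYWAQCWIEEDELGNAESSDIEINMNEANSWNAECDMDQPRNMC
CTVGSEWTRNCLTMPMQYRLPRSWEQMPDWHYWEMAHNFNYKPKL
>t26_22p_ref2 class=t26-22p-like synthetic
LTGHTTSAIIECQYMKNMRDCEICSYFDMWDPMQVAQMPKSPRVINRFKDRMCPHNMMEG
MHMQSYCASNLAYKILHHTQNQQGKCYPFQKLTQNVAYHGFCLTLKIICFGGAIKCWHLL
MYYISYAHYKIPNFYPNQYQYNHRFTDDPDINTNCYFVSFFLLYTNRSKILSYGPAYQLD
QRCTKGRVHQNQHHGGEQCELKEYNYKAKQWIEWPNMVNHWSYFHHLEKHINLVDMPMPM
KTWYRYITDPAAGTFNSYWAQPWIWEDELGNAESNDIEINMNEAQETNAEQDMDTPRNMC
AWVLSEFTRNCLTMFMQERLPRSWEGMSDQHYWEMANNFNYKPKCNGCGL
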